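"""Small shared helpers: seeding, standardization, validation."""

from __future__ import annotations

import numpy as np


def child_rng(seed: int, *stream: int) -> np.random.Generator:
    """Derive an independent generator from a master seed and stream offsets.

    Every source of randomness in the package goes through this helper so a
    single master seed reproduces the whole pipeline bit-exactly.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


def zscore(x: np.ndarray, ddof: int = 0) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=ddof)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


class ColumnScaler:
    """Per-column center/scale learned on training rows only.

    Constant columns get unit scale so they pass through as zeros instead of
    producing NaN.
    """

    def fit(self, X: np.ndarray) -> "ColumnScaler":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self.scale_ = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def check_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
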