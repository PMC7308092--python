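"""Scoring, chance baseline, paired model comparison and variable importance.

Cross-validated scores from the same dataset are not independent, so no
parametric test is attempted; instead, fold-wise paired differences under
the shared CV scheme are summarized by their mean, SD, central 95%
percentile interval and the fraction of splits in which the candidate
beats the reference (Pr<Ref, strict inequality — ties do not count as
wins). Chance level comes from a dummy regressor predicting the
training-fold mean under identical splits.

Three importance estimators are provided for the layer-2 forest:
in-sample permutation importance (error increase in outcome units when a
column is shuffled), its out-of-sample per-split variant, and mean
decrease impurity (MDI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def mae(pred, truth) -> float:
    """Mean absolute error in the units of the target (years of age)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("pred and truth must be non-empty and aligned")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(truth))):
        raise ValueError("non-finite inputs")
    return float(np.mean(np.abs(pred - truth)))


def dummy_baseline(y_train, y_test) -> np.ndarray:
    """Chance-level predictions: the training-set mean for every test case."""
    y_train = np.asarray(y_train, dtype=float)
    if y_train.size == 0:
        raise ValueError("empty training target")
    return np.full(len(np.asarray(y_test)), y_train.mean())


@dataclass
class FoldScores:
    """One MAE per (fold x repeat), aligned to a CV scheme key."""

    name: str
    values: np.ndarray
    cv_key: tuple

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_expected = self.cv_key[1] * self.cv_key[2]
        if len(self.values) != n_expected:
            raise ValueError(
                f"{self.name}: expected {n_expected} fold scores, "
                f"got {len(self.values)}")


@dataclass
class PairedComparison:
    candidate: str
    reference: str
    mean: float
    sd: float
    p2_5: float
    p97_5: float
    pr_better: float  # fraction of splits with candidate strictly better

    def __str__(self) -> str:
        return (f"{self.candidate} - {self.reference}: "
                f"M={self.mean:.3f}, SD={self.sd:.3f}, "
                f"P2.5,97.5=[{self.p2_5:.3f},{self.p97_5:.3f}], "
                f"Pr<Ref={100 * self.pr_better:.0f}%")


def paired_compare(a: FoldScores, ref: FoldScores) -> PairedComparison:
    """Summary of split-wise MAE differences a - ref under a shared scheme."""
    if a.cv_key != ref.cv_key:
        raise ValueError("fold scores come from different CV schemes")
    diff = a.values - ref.values
    lo, hi = np.percentile(diff, [2.5, 97.5])
    return PairedComparison(
        a.name, ref.name, float(diff.mean()), float(diff.std(ddof=1)),
        float(lo), float(hi), float(np.mean(diff < 0)))


def rank_models(scores: list[FoldScores]) -> pd.DataFrame:
    """Per-split model ranks (1 = lowest MAE; ties get the average rank).

    Returns a tidy frame with one row per (model, rank) giving the number
    of splits at that rank, plus pairwise strict-win fractions.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 models to rank")
    key = scores[0].cv_key
    if any(s.cv_key != key for s in scores):
        raise ValueError("fold scores come from different CV schemes")
    mat = np.vstack([s.values for s in scores])  # models x splits
    ranks = np.apply_along_axis(rankdata, 0, mat)
    n_splits = mat.shape[1]
    rows = []
    for i, s in enumerate(scores):
        uniq, counts = np.unique(ranks[i], return_counts=True)
        for r, c in zip(uniq, counts):
            rows.append({"model": s.name, "rank": float(r),
                         "n_splits": int(c), "of": n_splits})
    table = pd.DataFrame(rows)
    wins = {}
    for i, si in enumerate(scores):
        for j, sj in enumerate(scores):
            if i != j:
                wins[(si.name, sj.name)] = float(
                    np.mean(mat[i] < mat[j]))
    table.attrs["pairwise_wins"] = wins
    return table


def _perm_rng(seed: int, feature: int, k_index: int) -> np.random.Generator:
    # one stream per (feature, permutation index) for reproducibility
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(feature), int(k_index)]))


def permutation_importance(model, X: np.ndarray, y: np.ndarray,
                           k: int = 1000, seed: int = 0,
                           features=None) -> np.ndarray:
    """In-sample permutation importance in outcome units (years).

    importance_j = mean over k permutations of
    (MAE with column j shuffled - baseline MAE). Positive values mean the
    model relies on the feature; a feature the model ignores converges
    to 0 as k grows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    baseline = mae(model.predict(X), y)
    features = range(X.shape[1]) if features is None else features
    out = np.zeros(X.shape[1])
    for j in features:
        drops = np.empty(k)
        for rep in range(k):
            Xp = X.copy()
            Xp[:, j] = _perm_rng(seed, j, rep).permutation(Xp[:, j])
            drops[rep] = mae(model.predict(Xp), y) - baseline
        out[j] = drops.mean()
    return out


def permutation_importance_oos(fit_predict, X: np.ndarray, y: np.ndarray,
                               cv, k: int = 100, seed: int = 0) -> pd.DataFrame:
    """Out-of-sample permutation importance, one estimate per CV split.

    ``fit_predict(X_train, y_train)`` must return a fitted model with a
    ``predict`` method; test-split columns are shuffled k times per
    feature. Returns the per-feature mean and SD over the
    n_folds x n_repeats splits.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    per_split = []
    for rep in range(cv.n_repeats):
        for fold in range(cv.n_folds):
            tr = cv.train_indices(rep, fold)
            te = cv.test_indices(rep, fold)
            model = fit_predict(X[tr], y[tr])
            baseline = mae(model.predict(X[te]), y[te])
            imps = np.empty(X.shape[1])
            for j in range(X.shape[1]):
                drops = np.empty(k)
                for r in range(k):
                    Xp = X[te].copy()
                    Xp[:, j] = _perm_rng(seed + rep * 1000 + fold, j,
                                         r).permutation(Xp[:, j])
                    drops[r] = mae(model.predict(Xp), y[te]) - baseline
                imps[j] = drops.mean()
            per_split.append(imps)
    arr = np.vstack(per_split)
    return pd.DataFrame({"feature": np.arange(X.shape[1]),
                         "importance_mean": arr.mean(axis=0),
                         "importance_sd": arr.std(axis=0, ddof=1)})


def mdi_importance(model) -> np.ndarray:
    """Mean-decrease-impurity shares (MSE impurity), normalized to sum 1."""
    if not hasattr(model, "feature_importances_"):
        raise ValueError("model is not a fitted tree ensemble")
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    return imp / total if total > 0 else imp


def partial_dependence(model, X: np.ndarray, features, grid) -> np.ndarray:
    """Partial dependence by the clamp-and-average definition.

    ``features`` is one or two column indices; ``grid`` a vector (1-D
    case) or a pair of vectors (2-D case). Each output entry is the mean
    model prediction over the data with the selected feature(s) clamped
    to the grid point.
    """
    X = np.asarray(X, dtype=float)
    if np.isscalar(features):
        features = [features]
    features = list(features)
    for f in features:
        if not 0 <= f < X.shape[1]:
            raise ValueError(f"unknown feature index {f}")
    if len(features) == 1:
        grid = [np.asarray(grid, dtype=float)]
    else:
        grid = [np.asarray(g, dtype=float) for g in grid]
        if len(features) != 2 or len(grid) != 2:
            raise ValueError("2-D partial dependence needs two features "
                             "and two grid vectors")
    shape = tuple(len(g) for g in grid)
    out = np.empty(shape)
    for idx in np.ndindex(shape):
        Xc = X.copy()
        for f, g, i in zip(features, grid, idx):
            Xc[:, f] = g[i]
        out[idx] = model.predict(Xc).mean()
    return out
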