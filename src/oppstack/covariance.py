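"""Covariance-based power and connectivity features.

Covariance matrices of band-limited source signals live on the manifold of
symmetric positive-definite matrices; linear models on their raw entries
violate the geometry. The pipeline therefore (1) regularizes each
empirical covariance with closed-form Oracle Approximating Shrinkage
toward a scaled identity, (2) projects the shrunk matrices to the tangent
space at a reference point (affine-invariant geometric mean by default),
and (3) uses the tangent diagonal as log-power and the scaled strict lower
triangle as connectivity features. Orthogonalized envelope correlations —
which are not positive definite — bypass the tangent route and are
variance-stabilized with Fisher's z instead.

Band names follow the usual electrophysiology convention:
low, delta, theta, alpha, beta_low, beta_high, gamma_lo, gamma_mid,
gamma_high (ASCII aliases of low, δ, θ, α, β1, β2, γ1, γ2, γ3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.signal

from .simulate import MultichannelSignal

#: frequency-band definitions (Hz), Human-Connectome-Project style
BANDS = {
    "low": (0.1, 1.5),
    "delta": (1.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 15.0),
    "beta_low": (15.0, 26.0),
    "beta_high": (26.0, 35.0),
    "gamma_lo": (35.0, 50.0),
    "gamma_mid": (50.0, 74.0),
    "gamma_high": (76.0, 100.0),
}


@dataclass
class TangentVector:
    """Tangent-space image of a covariance matrix at the reference point."""

    diag_part: np.ndarray     # length p, log-variance scale
    offdiag_part: np.ndarray  # length p(p-1)/2, sqrt(2)-scaled lower triangle

    def __post_init__(self) -> None:
        self.diag_part = np.asarray(self.diag_part, dtype=float)
        self.offdiag_part = np.asarray(self.offdiag_part, dtype=float)
        p = len(self.diag_part)
        if len(self.offdiag_part) != p * (p - 1) // 2:
            raise ValueError("offdiag_part length must be p(p-1)/2")

    @property
    def p(self) -> int:
        return len(self.diag_part)

    def full(self) -> np.ndarray:
        """Reassemble the symmetric tangent matrix."""
        p = self.p
        S = np.diag(self.diag_part)
        il = np.tril_indices(p, k=-1)
        S[il] = self.offdiag_part / np.sqrt(2.0)
        S[(il[1], il[0])] = S[il]
        return S


def _check_spd(C: np.ndarray, name: str, tol: float = 1e-10) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"{name}: not square")
    if not np.allclose(C, C.T, atol=1e-8 * max(1.0, np.abs(C).max())):
        raise ValueError(f"{name}: not symmetric")
    w = np.linalg.eigvalsh(C)
    if w.min() <= tol:
        raise ValueError(f"{name}: not positive-definite (min eigenvalue {w.min():.3g})")
    return 0.5 * (C + C.T)


def oas_shrunk_covariance(X: np.ndarray,
                          alpha: float | None = None) -> tuple[np.ndarray, float]:
    """James-Stein-type shrinkage of the empirical covariance toward
    ``trace/p * I`` with the closed-form OAS shrinkage factor.

    Returns ``((1 - a) S + a tr(S)/p I, a)`` where ``S`` is the
    maximum-likelihood (1/n) covariance of the rows of ``X`` and ``a`` is
    the Oracle Approximating Shrinkage coefficient clipped to [0, 1]
    (``alpha`` forces a value instead). Constant data (zero trace) is an
    error.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    S = np.cov(X, rowvar=False, bias=True)
    S = np.atleast_2d(S)
    tr = np.trace(S)
    if tr <= 0:
        raise ValueError("constant data: covariance trace is zero")
    mu = tr / p
    if alpha is None:
        # closed-form OAS coefficient (the authors'-code variant, as used
        # in practice): mean(S^2) is trace(S@S)/p^2 for symmetric S
        mean_s2 = np.mean(S * S)
        num = mean_s2 + mu ** 2
        den = (n + 1.0) * (mean_s2 - mu ** 2 / p)
        alpha = 1.0 if den == 0 else min(num / den, 1.0)
    alpha = float(np.clip(alpha, 0.0, 1.0))
    return (1.0 - alpha) * S + alpha * mu * np.eye(p), alpha


def _sqrtm_sym(C: np.ndarray, inv: bool = False) -> np.ndarray:
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 1e-300, None)
    d = w ** (-0.5 if inv else 0.5)
    return (V * d) @ V.T


def _logm_sym(C: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(C)
    return (V * np.log(np.clip(w, 1e-300, None))) @ V.T


def _expm_sym(S: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(S)
    return (V * np.exp(w)) @ V.T


def geometric_mean(covs, tol: float = 1e-8, max_iter: int = 50) -> np.ndarray:
    """Affine-invariant (Karcher) mean of SPD matrices by fixed point.

    Iterates R <- R^1/2 exp(mean_i log(R^-1/2 C_i R^-1/2)) R^1/2 from the
    arithmetic mean. Falls back to the log-Euclidean mean with a warning if
    the iteration does not reach ``tol`` within ``max_iter`` steps.
    """
    covs = [np.asarray(C, dtype=float) for C in covs]
    R = np.mean(covs, axis=0)
    for _ in range(max_iter):
        R_half = _sqrtm_sym(R)
        R_ihalf = _sqrtm_sym(R, inv=True)
        T = np.mean([_logm_sym(R_ihalf @ C @ R_ihalf) for C in covs], axis=0)
        R = R_half @ _expm_sym(T) @ R_half
        if np.linalg.norm(T, "fro") < tol:
            return R
    warnings.warn("geometric mean did not converge; "
                  "falling back to the log-Euclidean mean", RuntimeWarning)
    return _expm_sym(np.mean([_logm_sym(C) for C in covs], axis=0))


def tangent_space(covs, reference="geometric_mean") -> list[TangentVector]:
    """Project SPD matrices to the tangent space at a reference point.

    S_i = logm(R^-1/2 C_i R^-1/2); the diagonal of S_i is the log-variance
    part and the strict lower triangle, scaled by sqrt(2), the connectivity
    part (the sqrt(2) weighting makes Euclidean distances between tangent
    vectors match the affine-invariant metric at the reference).
    """
    covs = [_check_spd(C, f"covariance #{i}") for i, C in enumerate(covs)]
    p = covs[0].shape[0]
    for i, C in enumerate(covs):
        if C.shape[0] != p:
            raise ValueError(f"covariance #{i}: dimension mismatch")
    if isinstance(reference, str):
        if reference != "geometric_mean":
            raise ValueError(f"unknown reference {reference!r}")
        R = geometric_mean(covs)
    else:
        R = _check_spd(reference, "reference")
    R_ihalf = _sqrtm_sym(R, inv=True)
    il = np.tril_indices(p, k=-1)
    out = []
    for C in covs:
        S = _logm_sym(R_ihalf @ C @ R_ihalf)
        out.append(TangentVector(np.diag(S).copy(), np.sqrt(2.0) * S[il]))
    return out


def tangent_space_inverse(tvs, reference) -> list[np.ndarray]:
    """Map tangent vectors back to SPD matrices at the same reference."""
    R = _check_spd(reference, "reference")
    R_half = _sqrtm_sym(R)
    return [R_half @ _expm_sym(tv.full()) @ R_half for tv in tvs]


def connectivity_values(tv: TangentVector) -> np.ndarray:
    """Off-diagonal tangent entries used as connectivity features.

    Length is exactly p(p-1)/2: 100,128 values for the 448-ROI cortical
    parcellation, 32,640 for a 256-ROI functional atlas.
    """
    return tv.offdiag_part


def fisher_z(r):
    """Fisher variance-stabilizing transform z = arctanh(r) =
    (1/2) log((1+r)/(1-r)), applied element-wise. Requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def envelope_correlation(signals, orthogonalize: bool = False,
                         fs: float | None = None) -> np.ndarray:
    """Power-envelope correlation matrix, optionally orthogonalized.

    ``signals`` is a p x samples array of raw band-limited time series (or
    a MultichannelSignal); envelopes are the Hilbert magnitudes. Without
    orthogonalization this is the plain Pearson correlation of the
    envelopes. With it, for each ordered pair (i, j) the zero-lag
    least-squares component of channel i is regressed out of the raw
    signal j before taking j's envelope, and the two directions are
    averaged — one member of the family of leakage-correction schemes. The
    diagonal is set to 1; a pair whose residual is (numerically) zero,
    e.g. identical signals, gets correlation 0 because the shared
    component is removed entirely. Zero-variance input channels yield NaN
    rows/columns.
    """
    if isinstance(signals, MultichannelSignal):
        fs = signals.fs
        data = signals.data
    else:
        data = np.atleast_2d(np.asarray(signals, dtype=float))
        fs = fs or 1.0
    p, n = data.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    sd = data.std(axis=1)
    degenerate = sd == 0

    def env(x):
        return np.abs(scipy.signal.hilbert(x))

    if not orthogonalize:
        E = np.vstack([env(data[i]) for i in range(p)])
        with np.errstate(invalid="ignore"):
            C = np.corrcoef(E)
        C[degenerate, :] = np.nan
        C[:, degenerate] = np.nan
        np.fill_diagonal(C, 1.0)
        return C

    envs = [env(data[i]) for i in range(p)]
    C = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            if degenerate[i] or degenerate[j]:
                C[i, j] = C[j, i] = np.nan
                continue
            rs = []
            for a, b in ((i, j), (j, i)):
                beta = np.dot(data[a], data[b]) / np.dot(data[a], data[a])
                resid = data[b] - beta * data[a]
                e_res = env(resid)
                if e_res.std() < 1e-12 * max(1.0, envs[a].std()):
                    rs.append(0.0)  # shared component fully removed
                else:
                    rs.append(np.corrcoef(envs[a], e_res)[0, 1])
            C[i, j] = C[j, i] = 0.5 * (rs[0] + rs[1])
    return C


def minimum_norm_operator(G: np.ndarray, lam: float) -> np.ndarray:
    """Minimum-norm inverse operator W = G^T (G G^T + lam I)^-1.

    ``G`` is the P-sensors x Q-sources forward (leadfield) matrix; applying
    the returned Q x P operator to sensor data yields source estimates.
    This is a ridge model predicting the field at each sensor from leadfield
    columns; ``lam`` controls the spatial smoothness of the solution.
    """
    G = np.asarray(G, dtype=float)
    if not np.all(np.isfinite(G)):
        raise ValueError("leadfield contains non-finite entries")
    if lam <= 0:
        raise ValueError("lam must be positive")
    P = G.shape[0]
    K = G @ G.T + lam * np.eye(P)
    # solve instead of explicit inverse for numerical hygiene
    return scipy.linalg.solve(K, G, assume_a="pos").T


def band_feature_name(family: str, band: str) -> str:
    """Canonical '<family>_<band>' feature naming, validated against BANDS."""
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; known: {sorted(BANDS)}")
    return f"{family}_{band}"
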