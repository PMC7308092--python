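"""Opportunistic two-layer stacking model for surrogate-biomarker learning.

Layer 1 fits one ridge regression per feature block (modality), with the
penalty tuned by generalized cross-validation over a 100-point log grid,
and produces out-of-fold age predictions under a shared 10-fold x
10-repeat cross-validation scheme. Missing modalities are then turned into
features by double-coding: every stacked column is duplicated, with
missing cells set to a low sentinel in one copy and a high sentinel in the
other (defaults -1000 / +1000 years — biologically impossible ages, so
trees can isolate missingness with a single threshold). Layer 2 is a
random-forest regressor trained on the coded out-of-fold predictions,
with tree depth and the per-split feature subsample tuned by an inner
5-fold grid search scored by mean absolute error. Any subject with at
least one observed modality can be used for training and prediction —
hence "opportunistic".

The public surface follows the Model/Results convention:
``StackedAgeModel(dataset).fit()`` returns a ``StackingResults`` carrying
out-of-fold predictions, fold-wise MAE scores for the stacked model, every
solo block and the chance baseline, selected hyper-parameters, and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from ._utils import ColumnScaler, child_rng
from .datasets import MultimodalDataset


# ---------------------------------------------------------------------------
# cross-validation scheme shared bit-exactly by both layers
# ---------------------------------------------------------------------------

@dataclass
class CVScheme:
    """Fold/repeat assignments consumed identically by layer 1 and layer 2.

    Each repeat reshuffles the subjects and partitions them into
    ``n_folds`` folds; the same index sets drive the ridge models, the
    forest, and the dummy baseline, which is what makes fold-wise paired
    comparisons meaningful.
    """

    n_subjects: int
    n_folds: int = 10
    n_repeats: int = 10
    seed: int = 0
    fold_of: np.ndarray = field(init=False)  # repeats x subjects fold index

    def __post_init__(self) -> None:
        if self.n_folds < 2 or self.n_folds > self.n_subjects:
            raise ValueError("n_folds must be in [2, n_subjects]")
        fold_of = np.empty((self.n_repeats, self.n_subjects), dtype=int)
        for rep in range(self.n_repeats):
            rng = child_rng(self.seed, 100 + rep)
            kf = KFold(self.n_folds, shuffle=True,
                       random_state=int(rng.integers(2 ** 31)))
            for f, (_, test_idx) in enumerate(kf.split(np.arange(self.n_subjects))):
                fold_of[rep, test_idx] = f
        self.fold_of = fold_of

    def test_indices(self, rep: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of[rep] == fold)

    def train_indices(self, rep: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of[rep] != fold)

    @property
    def n_splits(self) -> int:
        return self.n_folds * self.n_repeats

    def key(self) -> tuple:
        return (self.n_subjects, self.n_folds, self.n_repeats, self.seed)


# ---------------------------------------------------------------------------
# layer 1: ridge regression with GCV-selected penalty
# ---------------------------------------------------------------------------

@dataclass
class RidgeSpec:
    """Penalty grid and selection rule for the layer-1 ridge models."""

    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-3, 5, 100))

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        if np.any(np.diff(self.lambda_grid) <= 0):
            raise ValueError("lambda_grid must be strictly increasing")


class RidgeGCV:
    """Ridge regression with the penalty chosen by generalized CV.

    Inputs are standardized internally (center/scale learned on the
    training rows only) and the target centered, so the penalty acts on
    comparable coefficients. The whole regularization path is evaluated
    from one SVD: with X = U diag(s) V^T, the fit at penalty l has
    hat-matrix shrinkage factors s^2/(s^2 + l), giving residuals and the
    effective degrees of freedom df(l) = 1 + sum s^2/(s^2+l) (the 1 is the
    intercept). GCV(l) = (RSS/n) / (1 - df/n)^2; the smallest penalty wins
    ties.
    """

    def __init__(self, spec: RidgeSpec | None = None,
                 lam: float | None = None) -> None:
        self.spec = spec or RidgeSpec()
        self.forced_lam = lam

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RidgeGCV":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if p == 0:
            raise ValueError("empty design matrix")
        if not np.all(np.isfinite(X)):
            raise ValueError("X has missing/non-finite cells; layer-1 ridge "
                             "must be fit on observed rows only")
        if not np.all(np.isfinite(y)) or np.ptp(y) == 0:
            raise ValueError("degenerate target")
        self.scaler_ = ColumnScaler().fit(X)
        Xs = self.scaler_.transform(X)
        self.y_mean_ = y.mean()
        yc = y - self.y_mean_
        U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
        Uty = U.T @ yc
        lams = self.spec.lambda_grid
        shrink = s[None, :] ** 2 / (s[None, :] ** 2 + lams[:, None])
        fitted_norm2 = (shrink ** 2) @ (Uty ** 2)
        yc_norm2 = yc @ yc
        cross = shrink @ (Uty ** 2)
        rss = yc_norm2 - 2 * cross + fitted_norm2
        df = 1.0 + shrink.sum(axis=1)
        self.gcv_path_ = (rss / n) / (1.0 - df / n) ** 2
        if self.forced_lam is not None:
            lam = float(self.forced_lam)
        else:
            lam = float(lams[int(np.argmin(self.gcv_path_))])
        self.lambda_ = lam
        coef_std = Vt.T @ (s / (s ** 2 + lam) * Uty)
        self.coef_ = coef_std / self.scaler_.scale_
        self.intercept_ = self.y_mean_ - self.scaler_.mean_ @ self.coef_
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


# ---------------------------------------------------------------------------
# layer-1 out-of-fold predictions and double-coding
# ---------------------------------------------------------------------------

@dataclass
class StackedPredictions:
    """Out-of-fold layer-1 age predictions, kept separate per repeat.

    ``values[rep, i, j]`` is subject i's out-of-fold prediction from block
    j's ridge model in repeat rep (NaN where the block is unobserved);
    every observed cell is filled exactly once per repeat by a model that
    never saw that subject in that repeat.
    """

    values: np.ndarray  # n_repeats x n_subjects x m
    mask: np.ndarray    # n_subjects x m availability
    block_names: list[str]
    cv_key: tuple
    selected_lambdas: dict = field(default_factory=dict)

    @property
    def n_repeats(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[2]


def generate_oof(dataset: MultimodalDataset, cv: CVScheme,
                 spec: RidgeSpec | None = None) -> StackedPredictions:
    """Per-block ridge out-of-fold predictions under the shared CV scheme.

    For each (repeat, fold, block): fit on the observed training-fold rows
    of that block, predict its observed test-fold rows. Cells of
    unobserved (subject, block) pairs stay NaN in every repeat.
    """
    spec = spec or RidgeSpec()
    if cv.n_subjects != dataset.n_subjects:
        raise ValueError("CV scheme does not cover this dataset")
    if not dataset.observed_any().all():
        raise ValueError("subjects with zero observed modalities cannot be "
                         "stacked; drop them first (opportunistic learning "
                         "needs at least one block per subject)")
    m = len(dataset.blocks)
    values = np.full((cv.n_repeats, dataset.n_subjects, m), np.nan)
    mask = np.column_stack([blk.mask for blk in dataset.blocks.values()])
    lambdas: dict = {}
    for rep in range(cv.n_repeats):
        for fold in range(cv.n_folds):
            train = cv.train_indices(rep, fold)
            test = cv.test_indices(rep, fold)
            for j, (name, blk) in enumerate(dataset.blocks.items()):
                tr = train[blk.mask[train]]
                te = test[blk.mask[test]]
                if len(tr) < 2:
                    raise ValueError(
                        f"block {name!r}, repeat {rep}, fold {fold}: "
                        f"fewer than 2 observed training rows")
                model = RidgeGCV(spec).fit(blk.X[tr], dataset.age[tr])
                if len(te):
                    values[rep, te, j] = model.predict(blk.X[te])
                lambdas[(name, rep, fold)] = model.lambda_
    return StackedPredictions(values, mask, dataset.block_names, cv.key(),
                              lambdas)


def double_code(values: np.ndarray, mask: np.ndarray | None = None,
                sentinels: tuple = (-1000.0, 1000.0)) -> np.ndarray:
    """Double-code a subjects x m prediction matrix into 2m columns.

    Each column is duplicated; missing cells become ``sentinels[0]`` in
    the first copy and ``sentinels[1]`` in the second, observed cells are
    copied to both. Columns come in (low, high) pairs: output column 2j is
    the low copy of input column j, 2j+1 the high copy. Sentinels must lie
    outside the plausible prediction range; an observed value equal to a
    sentinel is ambiguous and raises.
    """
    lo, hi = sentinels
    if not lo < hi:
        raise ValueError("sentinel_low must be < sentinel_high")
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = ~np.isnan(values)
    mask = np.asarray(mask, dtype=bool)
    if np.any(np.isin(values[mask], [lo, hi])):
        raise ValueError("observed prediction equals a sentinel value")
    n, m = values.shape
    coded = np.empty((n, 2 * m))
    for j in range(m):
        col = values[:, j]
        low = np.where(mask[:, j], col, lo)
        high = np.where(mask[:, j], col, hi)
        coded[:, 2 * j] = low
        coded[:, 2 * j + 1] = high
    if np.isnan(coded).any():
        raise ValueError("masked-in cells contain NaN predictions")
    return coded


# ---------------------------------------------------------------------------
# layer 2: random-forest combiner with nested tuning
# ---------------------------------------------------------------------------

@dataclass
class ForestSpec:
    """Random-forest configuration for the layer-2 combiner.

    Defaults are the reference settings: 1000 trees, MSE splits, depth
    tuned over {4, 6, 8, unlimited} and the per-split feature count over
    {sqrt(p), log2(p), p} by an inner 5-fold grid search scored by MAE.
    Ties prefer the simpler model: smallest depth first, then the smallest
    realized max_features.
    """

    n_trees: int = 1000
    depth_grid: tuple = (4, 6, 8, None)
    max_features_grid: tuple = ("sqrt", "log2", 1.0)
    inner_cv: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.depth_grid or not self.max_features_grid:
            raise ValueError("tuning grids must be non-empty")


def _realized_max_features(mf, p: int) -> int:
    if mf == "sqrt":
        return max(1, int(np.sqrt(p)))
    if mf == "log2":
        return max(1, int(np.log2(p)))
    if isinstance(mf, float):
        return max(1, int(round(mf * p)))
    return int(mf)


def _make_forest(spec: ForestSpec, depth, mf, seed: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=spec.n_trees, criterion="squared_error",
        max_depth=depth, max_features=mf, random_state=seed, n_jobs=1)


def _tune_forest(X: np.ndarray, y: np.ndarray, spec: ForestSpec,
                 seed: int) -> tuple:
    """Inner grid search: 5-fold CV scored by MAE, simpler-model ties."""
    p = X.shape[1]
    if len(spec.depth_grid) == 1 and len(spec.max_features_grid) == 1:
        return spec.depth_grid[0], spec.max_features_grid[0]
    inner = KFold(spec.inner_cv, shuffle=True, random_state=seed % (2 ** 31))
    splits = list(inner.split(X))
    best = None
    for depth in spec.depth_grid:
        for mf in spec.max_features_grid:
            maes = []
            for tr, te in splits:
                forest = _make_forest(spec, depth, mf, seed % (2 ** 31))
                forest.fit(X[tr], y[tr])
                maes.append(np.mean(np.abs(forest.predict(X[te]) - y[te])))
            score = float(np.mean(maes))
            depth_key = np.inf if depth is None else depth
            cand = (score, depth_key, _realized_max_features(mf, p), depth, mf)
            if best is None or cand[:3] < best[:3]:
                best = cand
    return best[3], best[4]


@dataclass
class StackedModel:
    """Fitted layer-2 forest plus everything needed to predict new cases."""

    forests: list                      # one per repeat (final refits)
    layer1_models: dict                # block name -> RidgeGCV on all rows
    block_names: list[str]
    sentinels: tuple
    chosen_params: list                # per repeat (depth, max_features)
    oof_values: np.ndarray             # n_repeats x n_subjects layer-2 OOF
    cv_key: tuple


def fit_stacker(sp: StackedPredictions, y: np.ndarray, cv: CVScheme,
                spec: ForestSpec | None = None,
                sentinels: tuple = (-1000.0, 1000.0),
                tune: bool = True) -> StackedModel:
    """Fit the layer-2 forest on double-coded out-of-fold predictions.

    The forest is trained per repeat on that repeat's coded out-of-fold
    matrix, restricted to the layer-1 training folds of the shared
    ``CVScheme`` and scored on the matching test folds, so layer-2 test
    subjects are bit-identical to layer-1 test subjects. After the
    out-of-fold pass, one forest per repeat is refit on all rows (used for
    prediction on new cases).
    """
    spec = spec or ForestSpec()
    y = np.asarray(y, dtype=float)
    if sp.cv_key != cv.key():
        raise ValueError("StackedPredictions were made under a different CV scheme")
    if sp.values.shape[1] != len(y):
        raise ValueError("coded rows do not align with y")
    n = len(y)
    oof = np.full((cv.n_repeats, n), np.nan)
    forests, chosen = [], []
    for rep in range(cv.n_repeats):
        coded = double_code(sp.values[rep], sp.mask, sentinels)
        if np.ptp(y) == 0:
            # constant target: any forest predicts the constant
            depth, mf = spec.depth_grid[0], spec.max_features_grid[0]
        for fold in range(cv.n_folds):
            tr = cv.train_indices(rep, fold)
            te = cv.test_indices(rep, fold)
            seed = int(child_rng(spec.seed, rep, fold).integers(2 ** 31))
            if tune and np.ptp(y) != 0:
                depth, mf = _tune_forest(coded[tr], y[tr], spec, seed)
            elif np.ptp(y) != 0:
                depth, mf = spec.depth_grid[0], spec.max_features_grid[0]
            forest = _make_forest(spec, depth, mf, seed)
            forest.fit(coded[tr], y[tr])
            oof[rep, te] = forest.predict(coded[te])
        # final per-repeat refit on all rows for out-of-dataset prediction
        seed = int(child_rng(spec.seed, rep, cv.n_folds).integers(2 ** 31))
        if tune and np.ptp(y) != 0:
            depth, mf = _tune_forest(coded, y, spec, seed)
        else:
            depth, mf = spec.depth_grid[0], spec.max_features_grid[0]
        forest = _make_forest(spec, depth, mf, seed)
        forest.fit(coded, y)
        forests.append(forest)
        chosen.append((depth, mf))
    return StackedModel(forests, {}, sp.block_names, sentinels, chosen, oof,
                        cv.key())


def predict_opportunistic(model: StackedModel, blocks: dict) -> np.ndarray:
    """Predict age for new cases with arbitrary block availability.

    ``blocks`` maps block names to (X, mask) pairs; every subject must
    have at least one observed block, and each observed block needs a
    fitted layer-1 model. Layer-1 predictions for observed blocks are
    double-coded with the training sentinels and passed through the
    forests (mean over repeats). A complete-data subject follows exactly
    the same code path as the complete-data model.
    """
    if not model.layer1_models:
        raise ValueError("model carries no layer-1 models; "
                         "fit via StackedAgeModel to enable prediction")
    names = model.block_names
    for name in blocks:
        if name not in names:
            raise ValueError(f"unknown block {name!r}")
    first = next(iter(blocks.values()))
    n = np.asarray(first[0]).shape[0]
    values = np.full((n, len(names)), np.nan)
    mask = np.zeros((n, len(names)), dtype=bool)
    for j, name in enumerate(names):
        if name not in blocks:
            continue
        X, bm = blocks[name]
        X = np.asarray(X, dtype=float)
        bm = np.asarray(bm, dtype=bool)
        obs = np.flatnonzero(bm)
        if len(obs):
            values[obs, j] = model.layer1_models[name].predict(X[obs])
        mask[:, j] = bm
    if not mask.any(axis=1).all():
        raise ValueError("subject with zero observed blocks")
    coded = double_code(values, mask, model.sentinels)
    preds = np.mean([f.predict(coded) for f in model.forests], axis=0)
    return preds


def missingness_diagnostic(sp: StackedPredictions, y: np.ndarray,
                           cv: CVScheme, spec: ForestSpec | None = None,
                           sentinels: tuple = (-1000.0, 1000.0),
                           tune: bool = False) -> pd.DataFrame:
    """Is the missingness pattern itself informative of the target?

    Re-runs the opportunistic forest with observed cells zeroed and
    missing cells coded as usual, under the shared CV scheme, and returns
    the fold-wise paired comparison against the dummy (training-mean)
    baseline. Under MCAR the diagnostic should sit at chance; under
    age-dependent missingness it should beat the dummy.
    """
    spec = spec or ForestSpec()
    y = np.asarray(y, dtype=float)
    if sp.mask.all():
        raise ValueError("no missingness present; diagnostic undefined")
    zeroed = np.where(sp.mask, 0.0, np.nan)
    rows = []
    for rep in range(cv.n_repeats):
        coded = double_code(zeroed, sp.mask, sentinels)
        for fold in range(cv.n_folds):
            tr = cv.train_indices(rep, fold)
            te = cv.test_indices(rep, fold)
            seed = int(child_rng(spec.seed, 7000 + rep, fold).integers(2 ** 31))
            if tune:
                depth, mf = _tune_forest(coded[tr], y[tr], spec, seed)
            else:
                depth, mf = spec.depth_grid[0], spec.max_features_grid[0]
            forest = _make_forest(spec, depth, mf, seed)
            forest.fit(coded[tr], y[tr])
            mae_diag = float(np.mean(np.abs(forest.predict(coded[te]) - y[te])))
            mae_dummy = float(np.mean(np.abs(y[tr].mean() - y[te])))
            rows.append({"repeat": rep, "fold": fold,
                         "mae_diagnostic": mae_diag, "mae_dummy": mae_dummy})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

class StackedAgeModel:
    """Opportunistic stacked age-prediction model over a multimodal dataset.

    Parameters
    ----------
    dataset : MultimodalDataset
        Feature blocks with availability masks plus the age target.
    ridge_spec, forest_spec : optional
        Layer-1 and layer-2 configurations (paper defaults otherwise).
    sentinels : (low, high)
        Double-coding sentinel values, default (-1000, 1000) years.
    """

    def __init__(self, dataset: MultimodalDataset,
                 ridge_spec: RidgeSpec | None = None,
                 forest_spec: ForestSpec | None = None,
                 sentinels: tuple = (-1000.0, 1000.0)) -> None:
        self.dataset = dataset
        self.ridge_spec = ridge_spec or RidgeSpec()
        self.forest_spec = forest_spec or ForestSpec()
        self.sentinels = sentinels

    @classmethod
    def from_tables(cls, age_path, block_paths: dict, **kwargs) -> "StackedAgeModel":
        from .datasets import dataset_from_tables
        return cls(dataset_from_tables(age_path, block_paths), **kwargs)

    def fit(self, cv: CVScheme | None = None, tune: bool = True) -> "StackingResults":
        ds = self.dataset
        cv = cv or CVScheme(ds.n_subjects)
        sp = generate_oof(ds, cv, self.ridge_spec)
        stacked = fit_stacker(sp, ds.age, cv, self.forest_spec,
                              self.sentinels, tune=tune)
        # full-data layer-1 refits for out-of-dataset prediction
        for name, blk in ds.blocks.items():
            stacked.layer1_models[name] = RidgeGCV(self.ridge_spec).fit(
                blk.X[blk.mask], ds.age[blk.mask])
        return StackingResults(self, cv, sp, stacked)

    def predict(self, stacked: StackedModel, blocks: dict) -> np.ndarray:
        return predict_opportunistic(stacked, blocks)


class StackingResults:
    """Fit results: out-of-fold predictions, fold scores, diagnostics."""

    def __init__(self, model: StackedAgeModel, cv: CVScheme,
                 stacked_predictions: StackedPredictions,
                 stacked_model: StackedModel) -> None:
        self.model = model
        self.cv = cv
        self.stacked_predictions = stacked_predictions
        self.stacked_model = stacked_model

    # -- predictions ------------------------------------------------------

    @property
    def oof_prediction(self) -> np.ndarray:
        """Per-subject stacked prediction: mean over CV repeats."""
        return self.stacked_model.oof_values.mean(axis=0)

    @property
    def delta(self) -> np.ndarray:
        """Brain-age delta: predicted minus actual age (mean over repeats)."""
        return self.oof_prediction - self.model.dataset.age

    # -- fold-wise scores -------------------------------------------------

    def _fold_mae(self, pred_per_repeat: np.ndarray,
                  subset: np.ndarray | None = None) -> np.ndarray:
        """MAE per (fold x repeat) for an n_repeats x n_subjects array."""
        y = self.model.dataset.age
        out = np.empty(self.cv.n_splits)
        k = 0
        for rep in range(self.cv.n_repeats):
            for fold in range(self.cv.n_folds):
                te = self.cv.test_indices(rep, fold)
                if subset is not None:
                    te = te[subset[te]]
                p = pred_per_repeat[rep, te]
                ok = ~np.isnan(p)
                out[k] = np.mean(np.abs(p[ok] - y[te][ok]))
                k += 1
        return out

    def fold_scores(self) -> pd.DataFrame:
        """Fold-wise MAE for the stacked model, each solo block and chance.

        Solo-block scores are computed on that block's observed subjects
        within each test fold; the dummy baseline predicts the
        training-fold mean age under the identical splits.
        """
        ds = self.model.dataset
        y = ds.age
        cols = {"stacked": self._fold_mae(self.stacked_model.oof_values)}
        for j, name in enumerate(self.stacked_predictions.block_names):
            cols[f"solo_{name}"] = self._fold_mae(
                self.stacked_predictions.values[:, :, j])
        dummy = np.empty(self.cv.n_splits)
        k = 0
        for rep in range(self.cv.n_repeats):
            for fold in range(self.cv.n_folds):
                tr = self.cv.train_indices(rep, fold)
                te = self.cv.test_indices(rep, fold)
                dummy[k] = np.mean(np.abs(y[tr].mean() - y[te]))
                k += 1
        cols["dummy"] = dummy
        df = pd.DataFrame(cols)
        df.insert(0, "fold", np.tile(np.arange(self.cv.n_folds),
                                     self.cv.n_repeats))
        df.insert(0, "repeat", np.repeat(np.arange(self.cv.n_repeats),
                                         self.cv.n_folds))
        return df

    def coded_matrix(self, rep: int = 0) -> np.ndarray:
        return double_code(self.stacked_predictions.values[rep],
                           self.stacked_predictions.mask,
                           self.model.sentinels)

    def predict(self, blocks: dict) -> np.ndarray:
        return predict_opportunistic(self.stacked_model, blocks)

    def missingness_diagnostic(self, **kwargs) -> pd.DataFrame:
        return missingness_diagnostic(self.stacked_predictions,
                                      self.model.dataset.age, self.cv,
                                      self.model.forest_spec,
                                      self.model.sentinels, **kwargs)

    def summary(self) -> str:
        scores = self.fold_scores()
        lines = ["Opportunistic stacked age model",
                 "=" * 47,
                 f"subjects: {self.model.dataset.n_subjects}   "
                 f"blocks: {len(self.stacked_predictions.block_names)}   "
                 f"CV: {self.cv.n_folds} folds x {self.cv.n_repeats} repeats",
                 f"sentinels: {self.model.sentinels}",
                 "",
                 f"{'model':<24}{'MAE (y)':>10}{'SD':>8}"]
        for col in [c for c in scores.columns if c not in ("repeat", "fold")]:
            lines.append(f"{col:<24}{scores[col].mean():>10.2f}"
                         f"{scores[col].std(ddof=1):>8.2f}")
        params = pd.Series(
            [str(p) for p in self.stacked_model.chosen_params]).value_counts()
        lines += ["", "layer-2 (depth, max_features) per repeat:"]
        for val, cnt in params.items():
            lines.append(f"  {val}: {cnt} repeats")
        return "\n".join(lines)
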