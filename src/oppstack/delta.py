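"""Brain-age delta and its association with behavioral scores.

The brain-age delta of a subject is the out-of-fold predicted age minus
the chronological age; positive values mean the model overestimates the
subject's age, which across the literature correlates with poorer
physical and cognitive health. Because both the delta and most behavioral
scores depend on age itself, a naive correlation is confounded; three
deconfounding specifications are provided:

``two_step``  residualize the score on a cubic age polynomial, then
              regress the residual on the delta;
``joint``     one regression of the score on delta plus the cubic age
              terms;
``extended``  the joint model plus gender, binarized handedness and the
              log Frobenius norm of motion-parameter variability.

All continuous inputs are standardized so the reported beta_1 is a
standardized coefficient; in the two-step specification the residual is
re-standardized, making beta_1 exactly the Pearson correlation between
the residualized score and the delta. No multiple-testing correction is
applied; outputs annotate the conventional 5% / 1% / 0.1% reference
levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._utils import zscore

SPECIFICATIONS = ("two_step", "joint", "extended")
SIGNIFICANCE_LEVELS = (0.05, 0.01, 0.001)


def compute_delta(pred, age) -> np.ndarray:
    """delta = predicted age - actual age (positive = overestimation)."""
    pred = np.asarray(pred, dtype=float)
    age = np.asarray(age, dtype=float)
    if pred.shape != age.shape:
        raise ValueError("pred and age must be aligned")
    return pred - age


def _age_design(age_z: np.ndarray) -> np.ndarray:
    """Standardized cubic age polynomial columns."""
    return np.column_stack([zscore(age_z ** k) for k in (1, 2, 3)])


def residualize_score(score, age) -> np.ndarray:
    """Residual of the standardized score after a cubic age polynomial.

    Score and age are standardized first; the fit includes an intercept.
    The residual is orthogonal to (age, age^2, age^3) by construction.
    """
    score = np.asarray(score, dtype=float)
    age = np.asarray(age, dtype=float)
    if len(score) < 5:
        raise ValueError("need at least 5 subjects")
    design = sm.add_constant(_age_design(zscore(age)))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient age design")
    fit = sm.OLS(zscore(score), design).fit()
    return np.asarray(fit.resid)


@dataclass
class DeltaAssociationRow:
    score_name: str
    specification: str
    beta: float       # standardized coefficient on the delta
    p_value: float
    n: int

    def significance(self) -> str:
        """Reference-level annotation: one star per 5%/1%/0.1% level passed."""
        return "*" * sum(self.p_value < lv for lv in SIGNIFICANCE_LEVELS)


def delta_association(score, delta, age, confounds: dict | None = None,
                      spec: str = "two_step",
                      score_name: str = "score") -> DeltaAssociationRow:
    """Standardized association between a behavioral score and the delta.

    ``confounds`` (extended spec only) must provide 'gender',
    'hand_binary' and 'motion' columns; motion is entered as
    log(Frobenius norm of the motion-variability parameters).
    """
    if spec not in SPECIFICATIONS:
        raise ValueError(f"unknown specification {spec!r}")
    score = np.asarray(score, dtype=float)
    delta = np.asarray(delta, dtype=float)
    age = np.asarray(age, dtype=float)
    n = len(score)
    delta_z = zscore(delta)

    if spec == "two_step":
        resid = residualize_score(score, age)
        target = zscore(resid)
        design = sm.add_constant(delta_z)
    else:
        cols = [delta_z]
        names = ["delta"]
        if spec == "extended":
            if confounds is None or not {"gender", "hand_binary",
                                         "motion"} <= set(confounds):
                raise ValueError("extended spec requires gender, hand_binary "
                                 "and motion confounds")
            cols += [np.asarray(confounds["gender"], dtype=float),
                     np.asarray(confounds["hand_binary"], dtype=float),
                     zscore(np.log(np.asarray(confounds["motion"],
                                              dtype=float)))]
            names += ["gender", "hand_binary", "log_motion"]
        agez = zscore(age)
        cols += [zscore(agez ** k) for k in (1, 2, 3)]
        names += ["age", "age2", "age3"]
        design = sm.add_constant(np.column_stack(cols))
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            raise ValueError(f"collinear design; columns: {['const'] + names}")
        target = zscore(score)

    fit = sm.OLS(target, design).fit()
    return DeltaAssociationRow(score_name, spec, float(fit.params[1]),
                               float(fit.pvalues[1]), n)


def delta_association_table(scores: pd.DataFrame, delta, age,
                            confounds: dict | None = None,
                            specs=SPECIFICATIONS) -> pd.DataFrame:
    """Tidy association table: one row per score x specification."""
    rows = []
    for name in [c for c in scores.columns if c != "subject_id"]:
        for spec in specs:
            if spec == "extended" and confounds is None:
                continue
            r = delta_association(scores[name].to_numpy(), delta, age,
                                  confounds, spec, score_name=name)
            rows.append({"score": r.score_name, "specification": r.specification,
                         "beta": r.beta, "p_value": r.p_value, "n": r.n,
                         "significance": r.significance()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# score catalog
# ---------------------------------------------------------------------------

AGGREGATIONS = ("total", "mean", "ratio", "difference", "pc1", "raw")


@dataclass
class CatalogEntry:
    name: str
    type: str           # neuropsychology | physiology | questionnaire
    aggregation: str
    n_variables: int

    def __post_init__(self) -> None:
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"unknown aggregation tag {self.aggregation!r}")
        if self.n_variables < 1:
            raise ValueError("n_variables must be >= 1")


@dataclass
class ScoreCatalog:
    entries: list

    @property
    def total_variables(self) -> int:
        return sum(e.n_variables for e in self.entries)

    def names(self) -> list[str]:
        return [e.name for e in self.entries]


def build_score_catalog(spec: list) -> ScoreCatalog:
    """Build a catalog from (name, type, aggregation, n_variables) tuples."""
    return ScoreCatalog([e if isinstance(e, CatalogEntry) else CatalogEntry(*e)
                         for e in spec])


#: the shipped neurobehavioral score catalog: 23 measures, 38 variables
DEFAULT_CATALOG_SPEC = [
    ("benton_faces", "neuropsychology", "total", 1),
    ("emotional_expression_recognition", "neuropsychology", "pc1", 1),
    ("emotional_memory", "neuropsychology", "pc1", 3),
    ("emotion_regulation", "neuropsychology", "raw", 3),
    ("famous_faces", "neuropsychology", "ratio", 1),
    ("fluid_intelligence", "neuropsychology", "total", 1),
    ("force_matching", "neuropsychology", "difference", 2),
    ("hotel_task", "neuropsychology", "total", 1),
    ("motor_learning", "neuropsychology", "raw", 2),
    ("picture_priming", "neuropsychology", "raw", 4),
    ("proverb_comprehension", "neuropsychology", "total", 1),
    ("rt_choice", "neuropsychology", "mean", 1),
    ("rt_simple", "neuropsychology", "mean", 1),
    ("sentence_comprehension", "neuropsychology", "raw", 2),
    ("tip_of_the_tongue", "neuropsychology", "ratio", 1),
    ("visual_short_term_memory", "neuropsychology", "raw", 4),
    ("cardio_markers", "physiology", "raw", 3),
    ("psqi", "questionnaire", "total", 1),
    ("hours_slept", "questionnaire", "total", 1),
    ("hads_depression", "questionnaire", "total", 1),
    ("hads_anxiety", "questionnaire", "total", 1),
    ("ace_r", "questionnaire", "total", 1),
    ("mmse", "questionnaire", "total", 1),
]


def default_catalog() -> ScoreCatalog:
    return build_score_catalog(DEFAULT_CATALOG_SPEC)


def aggregate_subscores(sub: np.ndarray, how: str):
    """Aggregate a subjects x k sub-score matrix into final score(s).

    'total'/'mean' sum or average; 'ratio' and 'difference' need exactly
    two columns; 'pc1' returns the first principal component of the
    standardized sub-scores with the sign fixed so the largest-magnitude
    loading is positive, plus the explained-variance ratio; 'raw' returns
    the columns unchanged.
    """
    sub = np.asarray(sub, dtype=float)
    if sub.ndim == 1:
        sub = sub[:, None]
    if how == "total":
        return sub.sum(axis=1)
    if how == "mean":
        return sub.mean(axis=1)
    if how == "ratio":
        if sub.shape[1] != 2:
            raise ValueError("ratio needs exactly 2 sub-scores")
        return sub[:, 0] / sub[:, 1]
    if how == "difference":
        if sub.shape[1] != 2:
            raise ValueError("difference needs exactly 2 sub-scores")
        return sub[:, 0] - sub[:, 1]
    if how == "pc1":
        Z = np.column_stack([zscore(sub[:, j]) for j in range(sub.shape[1])])
        # SVD of the standardized sub-scores: first right singular vector
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        loading = Vt[0]
        if loading[np.argmax(np.abs(loading))] < 0:
            loading = -loading
        pc1 = Z @ loading
        ev_ratio = float(s[0] ** 2 / np.sum(s ** 2))
        return pc1, ev_ratio
    if how == "raw":
        return sub
    raise ValueError(f"unknown aggregation tag {how!r}")
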