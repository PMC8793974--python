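# Methods

## Model and procedure

The w-SVM is a two-stage classifier for binary outcomes on mixed tabular
data.

1. **Feature weighting.** Each predictor's point-biserial correlation
   with the ±1 outcome is computed by the group-mean form
   r = (X̄₊ − X̄₋)/S_X · √(p₊ p₋ n/(n−1)), which is exactly the Pearson
   correlation of the predictor against the outcome coded 0/1 (this
   identity is property-tested against a Pearson oracle). The weights
   are w_j = |r_j| / Σ_k |r_k|, so they are nonnegative, sum to one
   (unit-trace diagonal weight matrix), and are invariant to rescaling
   of the correlation vector. Categorical factors enter as their
   integer codes and receive a single correlation each; no one-hot
   expansion is performed, matching the single-weight-per-factor design
   of the method.
2. **Kernel machine.** The data matrix (optionally standardized, see
   below) is column-scaled, Z = X diag(w), and a soft-margin RBF SVM is
   trained on Z by maximizing the dual
   Σα − ½ΣΣ αᵢαⱼyᵢyⱼK(zᵢ,zⱼ) subject to 0 ≤ αᵢ ≤ C and Σαᵢyᵢ = 0,
   K(u,v) = exp(−γ‖u−v‖²). Prediction is sign(Σ αᵢyᵢK(zᵢ,z) + b) with
   sign(0) → +1 as the documented tie rule.

The dual as classically written for the separable case has only
α ≥ 0; this implementation always includes the box constraint α ≤ C
because the intended data are not separable and the cost parameter is
tuned alongside γ.

## Dual solver

The QP is solved by sequential minimal optimization with
maximal-violating-pair working-set selection on a precomputed kernel
matrix. Stopping rule: violating-pair gap m(α) − M(α) ≤ 1e-4 (a bound
on the KKT residual); hard cap of 200,000 pair updates, exceeded →
explicit solver error with diagnostics. Support vectors are the
coefficients with α > 1e-8·C; the bias is the mean of −yᵢ∇ᵢ over free
(0 < α < C) support vectors, falling back to the gap midpoint when no
free vector exists. Degenerate pair curvature (η ≤ 0, possible with
duplicated rows) is clamped to 1e-12. The solver is validated in the
suite against an independent generic constrained-QP solve (SLSQP) on
small random instances — agreement to < 1e-4 relative in the objective
— and against an explicit kernel-sum expansion of the decision values.

A useful exact identity used as a test oracle: uniform weights
w_j = 1/p at width γ give bit-for-bit the same kernel matrix as the
unweighted problem at width γ/p², hence identical fits.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| C | tuned (grid 2⁻³…2⁹, odd powers) | margin-violation cost |
| γ | tuned (grid 2⁻⁹…2¹, odd powers) | RBF width, on the weighted scale |
| tol | 1e-4 | dual KKT tolerance |
| standardize | on | z-score continuous columns with training stats |
| weights_mode | per-split | where the weights are estimated |
| tune_mode | nested | where (C, γ) are selected |
| k (tuning folds) | 10 | stratified CV folds for the grid search |

Tuning selects the candidate with minimal mean 10-fold validation
misclassification; ties prefer smaller C, then smaller γ (smoother
models). Continuous columns are z-scored using training-set statistics
before weighting because the RBF kernel is scale-sensitive and the
weights are meant to express association, not units; categorical codes
are left un-centred. Standardization does not change the correlations
(affine invariance), only the kernel geometry.

Two protocol questions are genuinely open in a single-table analysis and
are exposed as switches rather than guessed:

- **weights_mode** — `per-split` (default) recomputes weights inside
  every training portion, so no test information leaks into the
  weights; `full-data` computes them once on the whole table, mirroring
  a published single-table weight report.
- **tune_mode** — `nested` (default) re-tunes (C, γ) inside every
  training portion; `once` tunes a single time on the full table;
  `fixed` pins (C, γ).

## Evaluation protocol

MCCV draws stratified train/test partitions at a fixed training
fraction. Per-class training counts use largest-remainder rounding: the
total is the nearest integer to n·ratio, per-class floors are topped up
by descending fractional remainder (ties → larger class, then class
order). At n = 297 with a 137/160 split and ratio 0.80 this always
yields 238 train / 59 test. Iteration k's seed is derived from the
master seed by a counter-based SeedSequence spawn, so any iteration is
reproducible in isolation.

The seven indices are computed per iteration from the test-set confusion
matrix and averaged arithmetically across iterations (a pooled-count
report — one summed confusion matrix — is also attached to every MCCV
report). An index with a zero denominator in some iteration (possible
with very small test sets, e.g. a 95:5 split of ~300 records) is NaN
for that iteration and excluded from its mean, with the exclusion count
recorded; it is never silently zero.

The comparison harness evaluates all requested methods on the identical
split sequence (paired design). Baselines are scikit-learn's `SVC`
(library defaults), `RandomForestClassifier(n_estimators=200)` and
`GaussianNB`, fed the standardized but unweighted matrix.

## Synthetic data generator

The generator emulates the structure the method assumes: labels
Bernoulli(class_prob) mapped to ±1; continuous feature j drawn
N(δⱼ·y/2, 1), so δⱼ is the standardized between-class mean gap;
categorical feature j drawn from class-conditional category
probabilities. At a balanced split the population point-biserial of a
continuous feature is r = δ/(2√(1+δ²/4)), so target correlations are
directly encodable (`delta_for_correlation`). The bundled
`cleveland_like_spec` reproduces the shape of the heart-disease table —
n = 297, P(+1) = 0.461, five continuous and eight categorical
predictors — with effect sizes calibrated once from the published
correlation magnitudes and category splits shaped after the published
margins (near-null fasting blood sugar; strong thallium-defect and
vessel-count effects).

What the generator does *not* emulate: correlation between predictors
(columns are conditionally independent given the class), heavy tails or
skew in the continuous covariates, label noise beyond class overlap,
and missingness. Passing tests on synthetic data therefore demonstrate
correctness of the pipeline and recoverability of encoded effects, not
clinical performance on real tables.

## Numerical choices and edge cases

- All-zero correlation vectors (Σ|r| < 1e-10) are an error: the weight
  normalization is undefined.
- Inside resampling loops a training split can strand a constant
  column; the estimator assigns it zero correlation (it carries no
  class information there), while the standalone `point_biserial`
  refuses constant input. The transformer exposes the same choice as
  `constant_policy`.
- Weight ranks break ties by listed order (stable sort), so rank
  vectors are always a permutation of 1..p.
- Rounding of split sizes is exact integer arithmetic; no iteration
  ever changes the train/test sizes at a fixed ratio.

## Problem sizes in the shipped suite and example

The default test suite and the example configuration run MCCV with tens
of iterations, fixed or small tuning grids, and a few hundred samples —
sizes chosen so the whole suite completes in well under a minute on one
CPU while still exercising every mode (nested/once/fixed tuning,
per-split/full-data weights, all four comparison methods). A full
protocol run (five ratios × 1,000 iterations × nested 10-fold tuning
over the 42-point default grid) is a configuration change
(`ratios`/`n_iter`/`tune_mode` in the YAML), not a code change.

## Known limitations

- Weighting is marginal (one feature at a time): redundant correlated
  features each keep their full weight, and features informative only
  jointly are down-weighted.
- The point-biserial treats integer-coded factors as ordered; a
  genuinely nominal factor with an uninformative code ordering can be
  under-weighted.
- Binary outcomes only; no probability calibration; only the RBF kernel
  path is tuned.
- The real-data integration checks require the external UCI Cleveland
  file and are skipped when it is absent (`scripts/fetch_cleveland.py`
  documents the download).
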