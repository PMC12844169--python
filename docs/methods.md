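# Methods

## The problem

Single-cell ToF-SIMS metabolomics produces a samples × feature-ions
intensity matrix (summed per-cell ion counts or peak areas) that is
contaminated by non-biological structure: cells acquired at different
positions on a silicon wafer carry per-ion offsets, wafers measured on
different days (batches) differ more strongly still, and within one
acquisition sequence the signal drifts smoothly as the primary-ion beam and
surface state evolve.  Because the raw data carry no internal standards,
the only handle on these technical errors is the set of QC samples:
morphologically similar single cells interleaved through the sequence
(default one QC per four cells, with a QC at the start and end of the
sequence).  Any systematic structure in repeated QC measurements is, by
construction, technical.

## The two-stage correction

**Stage 1 — QC z-scoring (the Norm step).**  Each feature ion j is
standardized by the mean μ_j and standard deviation σ_j of the QC rows
only:

    z_ij = (x_ij − μ_j) / σ_j

Using QC statistics (rather than all-sample statistics) keeps biological
heterogeneity of the experimental cells out of the normalization
parameters and puts every ion's *technical* fluctuation on a unit scale.
σ uses the sample (n−1) denominator; ions with σ_j = 0 across QC carry no
calibratable signal and are dropped by default (an epsilon-floor mode is
available).  QC statistics are pooled across the whole dataset by default;
a per-batch-statistics mode exists for workflows that standardize each
batch independently.

**Stage 2 — QC-driven SVR (the drift model).**  For every feature ion an
ε-insensitive support-vector regression maps acquisition covariates to the
QC z-scores.  The design matrix contains the acquisition order scaled to
[0, 1] within each batch, followed by one-hot region indicators (sorted
lexicographically), then one-hot batch indicators.  Only QC rows enter the
fit; the fitted surface d̂_j is the estimated technical error, and the
correction subtracts it from every sample:

    z'_ij = z_ij − d̂_j(covariates_i),    x̂_ij = z'_ij · σ_j + μ_j

Subtraction in standardized space is equivalent to the additive raw-space
correction x̂ = x − σ_j·d̂; negative back-transformed intensities are
clipped to zero and counted.  Categorical levels (batch, region) unseen at
fit time are an error — drift is never extrapolated to an unseen batch.

Two genuinely open design choices are resolved as follows.  First, the
drift model regresses on *acquisition covariates*, not on correlated
feature intensities: the named error sources are spatial position and
instrument fluctuation, both functions of where/when a sample was
acquired, and covariate-based regression guarantees that cell intensities
cannot leak into the error model (verified by a permutation test).
Second, QC rows are corrected along with cell rows, so post-correction QC
diagnostics measure the residual technical error of the same pipeline the
cells went through.

**Hyperparameters.**  Per feature, an exhaustive grid search over
C ∈ {0.1, 1, 10, 100}, ε ∈ {0.01, 0.05, 0.1} and (RBF) γ ∈ {scale, 0.1,
1, 10} minimizes the mean 5-fold cross-validated squared error on the QC
rows; folds are shuffled with the configured seed (acquisition-contiguous
"blocked" folds are available for honest extrapolation assessment).  Exact
ties resolve to the least complex model: smallest C, then smallest ε, then
smallest γ.  The kernel defaults to RBF; a linear kernel is available and,
at ε → 0 and large C, reproduces the ordinary-least-squares drift line on
linear QC drift to within 1% slope error (tested).  When more than one
batch is present, one model set is fitted per batch (drift curves are
batch-specific); a pooled fit with batch indicators can be forced.

## Baseline

Total-area normalization — each row divided by its own total signal — is
the conventional ToF-SIMS baseline and is implemented as the comparator.
It removes per-sample global scale only; per-ion region/batch offsets and
ion-specific drift survive it, which is exactly what the diagnostics show.

## Diagnostics

* **RSD** per feature, separately over QC and cell rows:
  100·sd/mean (sample sd).  Zero-mean features get RSD = ∞, are flagged,
  and are excluded from every "fraction below threshold" denominator.
* **PCA** on mean-centered, by default unit-variance-scaled features
  (correlation PCA — raw and normalized tables are otherwise on
  incomparable scales).  Component signs are fixed by making each
  component's largest-magnitude loading positive.  A brute-force
  covariance eigendecomposition serves as the test oracle.
* **Batch/region mixing**: mean silhouette of the labels on the first two
  PC scores — a quantitative proxy for what a reader judges from a 2-D
  score plot.  Lower is better mixed.
* **Rank preservation**: per-sample Spearman correlation (average-rank
  ties) between uncorrected and corrected feature vectors, plus the OLS
  fit of log10 per-sample mean intensities after vs before.
* **LOESS ion trends**: tricube-weighted local *linear* regression
  (degree 1, no robustness iterations), span 0.75 by default, over
  acquisition order.

## Synthetic data generator

The generator emulates the two experimental designs the method targets —
one wafer with three acquisition regions, and three batches measured on
different days — with known ground truth.  Observation model per sample i
(batch b, region r, order t) and feature j:

    x_ij = p_ij · B_bj · R_brj · (1 + A·s_j(t/t_max)) · ε_ij

* p: drift-free profile.  Cells are log-normally heterogeneous around a
  per-feature base intensity (log10 means uniform on 2–5, biological
  CV 0.5 — single-cell metabolite signals are strongly dispersed); QC rows
  all share one reference profile ("same-size pseudo-cells", never blanks).
* B, R: per-feature log-normal batch and region factors (log-sd 0.6 and
  0.4).  These scales were calibrated once so the *raw* synthetic data
  qualitatively reproduce the phenomena the correction exists for:
  batches form clearly separated PCA clusters (silhouette ≈ 0.85) that
  total-area normalization barely reduces, and roughly half the QC ions
  exceed 50% RSD.  Factors are per-feature so that a row-sum normalization
  cannot remove them.  With a single batch (or region) the factors are
  identity — offsets are between-level effects.
* Drift: amplitude A = 0.4 (±40% relative), affecting 80% of features,
  with a smooth shape s scaled to [−1, 1] — exponential decay by default
  (typical beam/surface conditioning behavior), linear and sinusoidal as
  alternatives — and a random per-feature sign.  A homogeneous mode gives
  every affected feature the identical signed curve, realizing the limit
  in which the raw-space correction is a constant per sample and rank
  preservation is exact.
* ε: log-normal technical noise, CV 0.1 on QC and cell rows alike.
* Scheduling: one QC after every 4 cells, QC at both ends
  (n_qc = ⌈n_cells/4⌉ + 1, so 52 cells ⇒ 14 QC per batch); regions are
  contiguous blocks of the acquisition sequence.

Defaults reproduce the three-batch design: 3 × 52 cells + 14 QC each,
457 features.  All components (profiles, factors, drift curves, noise
draws) are stored, the observed table is composed from them (so
reconstruction is exact by construction), and a drift-free counterfactual
table can be produced.

**What the generator does not emulate:** correlated ion families
(fragments of one molecule), m/z-dependent drift structure, detector
saturation, ROI segmentation errors, or contaminated/abnormal QC cells.
Passing recovery tests on this generator therefore shows the pipeline
does what it claims under its own assumptions — smooth covariate-driven
drift, multiplicative offsets, honest QC — not that those assumptions hold
for any particular instrument.

## Numerical choices and degenerate inputs

* Peak screen: counts strictly > 1000, SNR ≥ 3.0, m/z ∈ [0, 824] Da, all
  configurable; when no per-ion annotations accompany a table, counts
  default to column sums and SNR to +∞ (screen passes vacuously, logged),
  since the screen is often applied upstream in vendor software.
* Acquisition order is 0-based; 1-based files are detected (min = 1) and
  shifted, logged.
* Fewer than 2 QC rows in a statistics scope, or fewer QC rows than CV
  folds in a fitting scope, is an error with an actionable message.
* The quantities reported by `scripts/acceptance.py` are computed on the
  default study design above; the determinism check uses a reduced design
  (2 × 16 cells, 20 features) and the linear-drift oracle check uses 50
  replicates of 20 QC points, sizes chosen so the whole script completes
  in minutes while every check still has adequate resolution.

## Known limitations

* With very few QC samples per batch (< 5) the default 5-fold CV cannot
  run; the fitter says so rather than silently degrading.
* The ε-tube means a truly flat QC signal can carry a fitted offset of up
  to ε; corrected values are unbiased only up to that tolerance.
* Per-feature grid search is O(features × grid × folds) SVR fits;
  the default design (457 features × 3 batches) takes a few minutes on
  one core.  The search loop is deliberately simple and deterministic.
* Rank preservation is exact only under feature-homogeneous drift; with
  heterogeneous drift the within-sample ordering of ions with similar
  intensities can legitimately change (median per-sample Spearman stays
  ≥ 0.95 on the default design).
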