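# Methods

## Problem setting

Gas chromatography–ion mobility spectrometry (GC-IMS) measures the volatile
organic compounds (VOCs) in a sample's headspace.  Each measurement is a
dense 2D intensity map — GC retention time × IMS drift time — in which
analytes appear as localised blobs and the reactant ion peak (RIP), produced
by continuous ionisation of the carrier gas, appears as an intense vertical
line at fixed drift position spanning all retention times.  `vocims`
implements the full desk-scale analysis for a two-group (case/control)
VOC-profiling study: spectrum simulation with planted class differences,
uniform preprocessing, cross-validated pixel-level feature selection and
classification, ROC diagnostics, and the prospective AUC-precision sample
size calculation.

## Spectrum model (synthetic data)

Each simulated spectrum on an `n_retention × n_drift` grid with axes
normalised to 0–100 is

```
I(r, d) = baseline
        + A_RIP · J · exp(−(d − d_RIP)² / 2σ_RIP²)
        + Σ_k  A_k · ρ_k^y · L_k · exp(−(r − r_k)²/2σ_rk² − (d − d_k)²/2σ_dk²)
        + ε(r, d),          ε ~ N(0, σ_noise²),   clamped at 0.
```

* Peaks are separable 2D Gaussians: the choice is not physically derived (real
  GC-IMS peaks are skewed by column tailing) but matches the blob appearance
  of real topographic plots and is analytically checkable pixel by pixel.
* `ρ_k` is the multiplicative class-1/class-0 intensity ratio of peak *k*
  (`y` the binary class label); peaks with `ρ ≠ 1` form the recorded ground
  truth.  Effect sizes for real faecal VOCs are unknown, so the defaults
  (ratio 2–3 in examples and checks) are simulation conditions, not
  estimates.
* `L_k` and `J` are mean-1 lognormal per-sample factors (lognormal keeps
  intensities positive); `amplitude_cv` is their coefficient of variation,
  default 0.3 — the order of biological inter-subject variation seen in
  headspace intensities.
* Default cohort sizes are 75 controls vs 109 cases, a realistic
  case/control imbalance for a paediatric IBD volatolomics study; the grid
  defaults to 64 × 64, far below instrument resolution but enough to contain
  well-separated peaks (the pipeline's cost is linear in pixels, so tests
  use 16–48 point grids).
* Negative intensities after noise are clamped to zero, as detectors report
  non-negative counts.  Sampling uses one independent child stream of the
  cohort seed per sample, so cohorts are bit-reproducible and order-stable.

What the generator does **not** emulate: monomer/dimer ion chemistry, RIP
depletion under analyte load, retention-time drift between injections, peak
skew, or heteroscedastic detector noise.  Passing tests therefore show the
statistical machinery is correct under the stated model, not that real
spectra meet its assumptions.

## Preprocessing

Fixed order — crop, RIP subtraction, static threshold — with one shared
configuration per cohort:

1. **Crop** to the axis window containing the chemical signal; windows are
   half-open `[lo, hi)` so adjacent windows tile without overlap.  The
   window is a configuration value (with a plotting-free pipeline there is
   no interactive inspection step).
2. **RIP line**: the element-wise mean over the retention rows of a
   configured window that contains the RIP but no analyte signal (default:
   the top rows of the crop).  Default mode recomputes the line per sample
   at the shared window, because RIP amplitude varies per injection; a
   `global` mode takes one line from the cohort-mean spectrum for strict
   one-line-for-all-files behaviour.  The line is subtracted from every row
   and negatives are clamped to zero so the subsequent threshold stays
   well-defined on non-negative data.
3. **Threshold**: intensities strictly below τ are zeroed (values equal to
   τ survive).  `"auto"` sets τ to 3× the median positive intensity after
   RIP subtraction — an implementation default tracking the noise floor,
   not a measured instrument value.

The chain is idempotent on noise-free data, preserves non-negativity at
every stage, and logs the settings actually applied.

## Feature pipeline

Preprocessed spectra are flattened row-major into a samples × pixels table.
A stratified k-fold split (default k = 10) is drawn once, seeded.  Within
each fold:

* every pixel gets a two-sided Wilcoxon rank-sum p-value computed **on the
  training rows only** — this is the leakage guard; ranking on the full
  table inflates apparent AUC even on pure noise (the test suite keeps a
  deliberately leaky variant to demonstrate the asymmetry);
* the `n_top_features` lowest-p pixels (default 50 — how many features a
  real analysis would keep is a free choice) enter the classifier, ties in
  p broken by ascending flat index for determinism;
* the classifier is either **sparse logistic regression** (L1-penalised,
  liblinear; penalty strength chosen by 5-fold CV *inside the training
  fold*, preserving the leakage guarantee; features standardised on the
  training fold) or **gradient boosting** (xgboost: depth 3, 200 rounds,
  learning rate 0.1, subsample 0.8, seeded);
* held-out rows receive class-1 probabilities.

Pooling the held-out probabilities over folds gives one out-of-fold
probability per sample, from which a single ROC is computed — pooling (rather
than averaging per-fold AUCs) yields one curve with a well-defined CI and a
per-sample score vector for the rank-sum p-value.

Rank-sum p-values use exact enumeration when the combined group size is at
most 12 with no ties, otherwise the normal approximation with tie and
continuity corrections; the vectorised per-pixel path is tested for exact
agreement with the scalar reference.

## Diagnostics

From pooled out-of-fold probabilities: AUC (Mann–Whitney pair statistic),
95% CI (DeLong by default — standard for empirical AUCs; Hanley–McNeil
closed form as the alternative), a two-sided Mann–Whitney p-value for
H₀: AUC = 0.5, the Youden-optimal cutoff (J = sensitivity + specificity − 1,
ties resolved toward higher specificity then lower cutoff, J compared with
1e-9 tolerance because equal count-ratios can differ in the last float ulp),
and sensitivity/specificity/PPV/NPV at that cutoff under the rule
`score ≥ cutoff`.  Ratios with empty denominators are reported as NaN, never
as 0.  PPV/NPV are computed from the observed confusion table, i.e. at the
study prevalence.

**Design calculation.**  For a prospective study, the expected two-sided CI
width at confidence level ℓ is `2 · z_ℓ · SE_HM(A, n_pos, n_neg)` with the
Hanley–McNeil standard error evaluated at the postulated AUC.  The case
group carries the Q1 term, so group order matters under imbalance
(123 cases / 62 controls at A = 0.87 gives width 0.10; swapped, 0.12).  The
design domain is restricted to A ∈ [0.5, 1).

## Numerical and design choices

* Seeds: one global seed fans out to per-stage seeds via independent
  `numpy.random.SeedSequence` child streams (simulation first, CV second);
  derived seeds are reduced below 2³¹ for library compatibility.
* Fold assignment uses scikit-learn's (Stratified)KFold with shuffling;
  stratified mode requires k ≤ minority-class count.
* The inner CV for the logistic penalty shrinks to the minority-class count
  of the training fold when that is below 5.
* Degenerate inputs raise typed errors (window/shape/cohort/config/
  stratification/input/parse) that the CLI maps to distinct exit codes.

## Problem sizes used in checks

The repository's statistical checks run on reduced problem sizes chosen to
exercise the same conditions at desk scale: pure-noise leakage runs use 60
samples × 2025 pixels over 20 seeded replicates; null type-I runs use 50 + 50
samples on a 16 × 16 grid over 200 replicates; planted-effect recovery uses
40 + 40 samples on a 48 × 48 grid; bootstrap verification of the design
width uses 2000 resamples.

## Known limitations

* Binary class labels only; multi-group comparisons are run pairwise.
* No multiple-testing correction across comparisons and no probability
  calibration analysis.
* No vendor binary format ingestion: spectra are exchanged as dense CSV.
* The Hanley–McNeil variance is an approximation that degrades for AUC near
  0.5 with tiny groups; DeLong is preferred for empirical intervals.
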