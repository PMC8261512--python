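# Methods

This note documents the models and procedures `noduleomics` implements,
the defaults and why they were chosen, what the synthetic cohort
generator does and does not emulate, and the numerical decisions taken
where the design was genuinely open.

## Pipeline model

The package follows a two-phase supervised design. In the discovery
phase, every fitted object — QC thresholds aside, which are fixed —
derives from the discovery cohort only: the preprocessing parameters
(per-feature log₂(x+1) medians for imputation, means and standard
deviations for z-scoring), the MCB segmentation, the consensus marker
set, the RFECV feature subset, the SVM hyperparameters and Platt
calibration, the per-platform binarization cutoffs, and the
Bernoulli-naive-Bayes conditionals and priors. In the validation phase
these artifacts are applied frozen; the `score` and `evaluate` CLI
commands cannot fit anything. This is what makes the validation AUC an
honest generalization estimate.

### MCB segmentation

A methylation-correlated block is a maximal run of at least `min_sites`
(default 3) CpG sites on one chromosome in which every adjacent pair is
at most `max_gap` (default 100) bp apart and has Pearson correlation at
least `min_r` (default 0.9) in the benign samples and in the malignant
samples separately. Decisions inside that rule:

- Gap is `pos(next) − pos(current)` with an inclusive `≤ 100` bound.
- Correlations use pairwise-complete samples (missingness arises from
  the depth filter). A pair with fewer than 3 complete sample pairs has
  an undefined correlation and is treated as no link (logged). The
  3-pair floor is a package choice; nothing in the underlying method
  dictates a minimum.
- The per-pair link requires the threshold in *each* group, not on the
  pooled cohort: pooled correlation can be induced by a group mean shift
  alone, which is exactly what the block summary is later asked to
  detect, so pooling would bias segmentation toward differential regions.
- Blocks are maximal runs of linked sites; the link relation is
  deterministic, so no tie-breaking is needed and blocks cannot overlap.
- Coordinates are 1-based in memory and in TSV (the convention of
  bisulfite callers); only the BED export converts to 0-based half-open.

QC precedes segmentation: measurements with depth < 100× are dropped
(strict `<`), and surviving measurements with < 2 supporting methylated
reads keep the row with beta replaced by 0 — a sub-2-read methylation
signal at 100× is indistinguishable from bisulfite-conversion failure.

### Mutation features

The four-level classification is an ordered first-match rule; hotspot
membership and deleteriousness are *input annotations* (the external
resources that define them are upstream of this package; a small demo
gene-role table ships for the generator). The per-sample vector is
dense: an empty level contributes count 0 and max-VAF 0 rather than a
missing value, because a VAF of 0 is semantically "no tumor signal" and
downstream z-scoring needs dense columns. VAF is a fraction in [0,1];
percent-formatted input is rejected rather than rescaled, since silent
rescaling hides unit bugs.

### Consensus univariate screening

Six two-sided tests at α = 0.1 with a ≥ 4-of-6 consensus and no
multiplicity correction — the consensus is the guard. Numerical
conventions, all logged because the test battery names two synonymous
rank tests:

- Wilcoxon slot: normal approximation with continuity correction.
- Mann–Whitney slot: exact when both groups ≤ 25, else asymptotic
  without continuity correction. The two slots therefore give distinct
  p-values for the same rank statistic.
- Fisher and chi-square require a contingency table; continuous features
  are dichotomized at the pooled-sample median (the least-parameterized
  choice). Categorical features use their native table. Chi-square
  applies the Yates correction on 2×2 tables and Fisher is the standard
  exact test — the conventions of the R functions practitioners use.
- Degenerate inputs (constant feature, empty table margin) yield p = 1
  with a warning instead of an error, so screening never aborts on a
  dead feature.

A consequence worth knowing: on a fixed-margin median-split table the
exact and Yates-corrected tests are conservative (type-I error ≈ 0.04 at
α = 0.1, from p-value discreteness), so the effective consensus demands
the four continuous-location tests almost jointly. The measured
per-feature null consensus rate at 28/70 is ≈ 8%.

### Platform classifiers

Transform order is fixed: log₂(x+1) → record discovery medians of the
transformed values → impute → record mean/std of the imputed transformed
table → z-score. Zero-variance features are dropped and recorded.
Applying a transform to an already-transformed table raises — a double
log-z-score silently corrupts scales and is a real failure mode of
frozen-parameter pipelines.

The SVM is linear-kernel throughout. Out-of-fold evaluation uses
stratified 13-fold CV (13 is retained as the workflow's stated
convention; folds are stratified, and the fold count drops to the
smallest class size with a warning when a class is smaller than 13).
Within each training part, C is chosen by exhaustive grid search
(log-spaced 10⁻³…10³, a package choice) on stratified 60/40
shuffle-splits, and probabilities come from a sigmoid (Platt) fit to the
training-fold margins — probability-scale cutoffs downstream need
calibrated scores, and Platt is the minimal calibration for a linear
margin. The deliverable model is refit on the full discovery cohort.

RFECV consensus: 20 repeats, each a full recursive elimination ranked by
linear-SVM weights and validated on 10 stratified shuffle-splits with a
test fraction drawn uniformly from [0.20, 0.40]; the consensus keeps
features selected in a majority of repeats. The elimination estimator
uses C = 0.1: with weak regularization the max-margin solution can
concentrate weight on a subset of redundant informative features, and
RFE then discards genuinely informative ones; moderate L2 spreads the
weights so rankings track informativeness.

The clinical platform is the univariate age model by default (the
multivariate clinical combinations underperform it); the pipeline still
accepts multivariate clinical input.

### Bernoulli naive-Bayes integration

The four platform probabilities are binarized at each platform's own
discovery-optimal (sensitivity+specificity-maximizing) cutoff — the
calibrated score scales differ across platforms, so a shared 0.5 would
mis-binarize — and combined by Bayes' rule with Laplace smoothing
(α = 1; the choice is exposed). Posteriors are computed in log space and
normalized exactly over the two classes. The per-platform importance
weight is the mean posterior probability a single-platform reduction of
the fitted integrator assigns to each sample's true class: bounded in
[0,1], 0.5 for an uninformative platform under balanced priors, → 1 for
a perfectly informative one as smoothing vanishes. It is a summary of
the fitted conditionals, not a claim about any particular published
weight definition.

### ROC study design

For the one-ROC-curve test the binormal model with slope b = 1 maps the
alternative AUC to a = √2·Φ⁻¹(AUC). The variance of the estimated
full-curve AUC follows by the delta method from the continuous-scale
binormal component variances

    var(â)  = (a² + 2 + 2b²/R) / (2 n_dis)
    var(b̂)  = b²(1 + 1/R) / (2 n_dis)
    cov(â,b̂) = a·b / (2 n_dis)

with R the non-diseased:diseased allocation ratio, mapped through
A = Φ(a/√(1+b²)). The returned n is the smallest integer satisfying

    AUC₁ − AUC₀ ≥ z₁₋α/₂·√V₀(n) + z_power·√V₁(n).

The default is **two-sided**: with these variances the canonical design
(AUC 0.85 vs 0.5, α 0.05, power 0.90, R = 1) requires n = 10.2 → 11 per
group two-sided and 9 one-sided; the widely used software module this
mirrors reports 11, which pins the two-sided convention. The popular
closed-form approximation 0.0099·e^(−a²/4)·(5a²+8+(a²+8)/R) is
deliberately conservative (it carries e^(−a²/4) where the delta method
gives e^(−a²/2) in f²) and yields 12; it is not used. The Monte-Carlo
confirmation draws binormal scores, plugs group means/sds into the
binormal AUC estimate, and tests with the same null-variance z statistic;
empirical power at n = 11 is ≈ 0.90.

Classification is strict `score > threshold` everywhere, consistent with
the SUVmax > 2.5 convention, and cutoff ties are broken toward the
higher threshold (higher specificity — the clinical goal of this kind of
test is specificity on benign nodules).

## Synthetic cohort generator

The generator is the package's study-condition definition: a labeled
two-group cohort (defaults 28 benign / 70 malignant) whose four data
types carry the statistical structure each downstream stage assumes.
Every generator is a pure function of (spec, seed); defaults live in a
versioned YAML shipped with the package.

- **Clinical**: group-specific Gaussians for age (51.8 ± 8.0 vs
  58.7 ± 8.1 years) and nodule axes, group-specific Bernoulli draws for
  the binary features, matching the demographic table the cohort
  emulates; two derived size features are appended.
- **Proteins**: eight positive log-normal markers (σ_log = 0.8); three
  (CEA, CYFRA 21-1, SCC) carry malignant log-shifts of 0.66/0.55/0.50,
  placing their univariate AUCs at ≈ 0.71/0.68/0.68 — the reported
  discovery range — and the other five are null.
- **Mutations**: per-level Poisson counts with near-identical group
  rates (benign 12.5 vs malignant 13.5 calls/sample in total, cohort
  median ≈ 13) and near-identical low-VAF Beta distributions, so the
  mutation platform sits near chance, as observed for plasma panels at
  this depth; annotation fields are drawn consistently with the level
  rules, so generated levels round-trip through the classifier exactly.
- **Methylation**: a logit-normal latent-factor model. Each
  (sample, block) draws a shared latent level (sd 1.0) and each site
  adds independent logit-scale noise (sd 0.10), giving a true
  within-block adjacent-site correlation of ≈ 0.99 — calibrated so the
  minimum *sample* correlation at discovery group sizes stays above the
  0.9 link rule (measured minimum 0.949 over 25 replicate cohorts) and
  the planted block map is exactly recoverable. Block baselines are
  uniform in [0.2, 0.6]; 25 % of blocks are discriminative with a
  planted mean-beta shift δ = 0.2. Logit locations are calibrated by
  Gauss–Hermite quadrature so the *expected beta* equals the target —
  group differences recover δ without transform bias. The malignant
  shift is scaled per sample by a tumor-signal factor (Bernoulli
  shedding, p = 0.85, × Gamma magnitude, CV 0.5, normalized to mean 1):
  ctDNA shedding heterogeneity is what keeps the multivariate
  methylation AUC realistic (~0.9 at these settings) instead of
  saturating as planted blocks accumulate. Depth is lognormal
  (median ≈ 500×) and methylated reads are round(beta × depth), which
  makes the read-count QC rule exercisable.
- **Platform scores** (integration-level toy): each platform score is a
  logistic transform of an independent noisy view of the disease state
  with platform-specific separation d (AUC ≈ Φ(d/√2)); the default
  separations 0.95/0.8/0.3/1.3 mirror the reported per-platform AUC
  ordering. For the stacking-gain property test the balanced condition
  d = 1.0 for all four platforms is used instead: exact enumeration of
  the 16 vote patterns shows the balanced condition carries a population
  stacking gain of +0.10 (vs +0.03 for the mirrored condition), well
  above the replicate noise of an AUC difference at n = 98, so the test
  actually has power to detect a broken integrator.

What the generator does **not** emulate: read-level data (no FASTQ/BAM;
simulation starts at called beta values and annotated calls), inter-block
correlation structure, batch effects, assay drift between cohorts,
covariate-dependent missingness, and any mechanistic cfDNA biology. A
green pipeline on synthetic data therefore demonstrates the *statistical
machinery* — segmentation, selection, honest CV, stacking, design — not
clinical performance on real plasma.

## Numerical choices and degenerate inputs

- AUC is the rank statistic with mid-rank tie handling; orientation is
  not forced (an AUC below 0.5 is reported as such).
- Bootstrap CIs are stratified percentile intervals (class sizes are
  preserved, so resamples cannot degenerate); the DeLong variance is
  available as a cross-check.
- Cutoff optimization scans observed values and adjacent midpoints
  exhaustively; equality of the objective resolves to the higher
  threshold.
- Posterior computation is in log space with a max-subtraction, exact to
  normalization.
- Seeds: every stochastic routine takes an explicit seed; generators
  derive independent per-stage streams from (seed, stage index), so
  adding a stage never perturbs another stage's draws.

## Problem sizes

Tests and the acceptance script run on deliberately small instances
chosen to measure each property with adequate precision: 20 replicate
cohorts (≈ 800 blocks) for recovery rates, 50 replicates for the
stacking property, 1000 null features for test calibration, 5000
Monte-Carlo replicates for design power, and oracle sweeps of ≤ 100
sites / ≤ 200 samples where exhaustive enumeration is the reference.

## Known limitations

- The Fisher and Yates chi-square slots are conservative on median-split
  tables (see above); the consensus rule inherits this.
- The 13-fold convention leaves ~2 benign samples per fold at 28/70;
  fold-level estimates are noisy and only the pooled out-of-fold score
  is reported.
- The RFECV consensus varies the validated subset size across repeats,
  but the elimination ranking within a repeat is computed on the full
  table, so repeats agree more than fully independent reruns would.
- The importance-weight definition is package-specific (documented
  above) and not comparable across studies.
- Supplementary per-patient tables from the study this workflow models
  are not bundled; readers for their layouts are provided and tested on
  synthetic stand-ins only.
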