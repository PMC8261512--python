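# noduleomics

Low-dose CT screening finds far more pulmonary nodules than cancers: most
high-risk nodules sent to resection turn out benign (tuberculomas,
hamartomas, inflammation). `noduleomics` implements, as a tested Python
library, the analytical workflow of a noninvasive blood-based diagnosis
study for such nodules: per-platform malignancy classifiers built from
clinical features, serum protein markers, plasma cfDNA somatic mutations
and cfDNA methylation, stacked into one integrative probability of
malignancy, together with the ROC power analysis used to size a
validation cohort. A bundled synthetic cohort generator reproduces the
statistical structure every stage assumes, so the whole pipeline runs and
is tested end to end without any data download.

It is written for computational biologists and biostatisticians who want
to reuse the individual components (block segmentation, consensus
screening, stacked integration, ROC design) or to prototype the full
two-phase discovery/validation workflow.

## The method

**Methylation-correlated blocks (MCBs).** CpG sites are QC-filtered
(sites with depth < 100× removed; beta of sites with < 2 supporting
methylated reads set to 0) and segmented into blocks: maximal runs of
≥ 3 sites in which every adjacent pair is ≤ 100 bp apart and has Pearson
r ≥ 0.9 across samples in the benign group *and* in the malignant group.
A block's methylation level per sample is the mean beta of its member
sites.

**Mutation functional levels.** Each somatic call is assigned the first
matching level — L1: oncogene variant in the core hotspot list; L2:
tumor-suppressor variant in the hotspot list or otherwise predicted
deleterious; L3: remaining exonic nonsynonymous; L4: everything else —
and each sample is summarized by eight numbers: per-level call count and
per-level maximal variant allele frequency.

**Consensus marker screening.** Each candidate feature is tested with six
univariate tests (ANOVA, Fisher's exact, chi-square, Wilcoxon rank-sum,
Mann–Whitney, Student's t, all two-sided); a feature is a candidate
marker iff p < 0.1 in at least 4 of the 6. Univariate AUC is reported for
reference only.

**Platform classifiers.** Features are transformed log₂(x+1), imputed
with discovery medians, z-scored with discovery mean/std (validation data
is transformed with the frozen parameters, never refit). Methylation
features pass through repeated recursive feature elimination (20 repeats
of stratified shuffle-split CV, 10 splits, 20–40 % test size; majority
consensus). Each platform is a linear-kernel SVM with grid-searched
regularization (stratified 60/40 shuffle splits) and Platt-calibrated
probabilities, evaluated by stratified 13-fold out-of-fold prediction and
bootstrap AUC.

**Bernoulli naive-Bayes stacking.** The four platform probabilities are
binarized at each platform's own sensitivity+specificity-optimal cutoff
and combined by a Bernoulli naive-Bayes layer with Laplace smoothing:

  P(malignant | v₁..v₄) ∝ π_mal · Πₖ P(vₖ | malignant)

normalized over the two classes. Per-platform importance weights (mean
single-platform posterior on the true class) are reported alongside.

**ROC study design.** The one-ROC-curve sample-size computation follows
the binormal Obuchowski–McClish model: the alternative AUC maps to a
binormal separation a = √2·Φ⁻¹(AUC) (slope b = 1), the variance of the
estimated AUC comes from the delta method over the binormal parameter
estimates, and the smallest per-group n satisfying the two-sided
normal-theory power inequality is returned and confirmed by Monte-Carlo
simulation. A SUVmax > 2.5 PET/CT baseline classifier is included as the
conventional comparator.

## Worked example

Scripts under `examples/` exercise one capability each. Sizing a
validation cohort (`examples/07_study_design.py`):

```text
to confirm AUC 0.85 vs 0.5 (alpha 0.05, power 0.90): 11 malignant and 11 benign samples
Monte-Carlo power at that size: 0.902 (5000 replicates)
```

Eleven samples per group is the smallest design whose analytic power
reaches 0.90 for detecting AUC 0.85 against chance; the simulated power
at that size confirms the normal-theory computation.

Stacking four complementary platform scores
(`examples/06_integration.py`):

```text
clinical_score       AUC = 0.851
protein_score        AUC = 0.795
mutation_score       AUC = 0.686
methylation_score    AUC = 0.832
integrated (OOF)     AUC = 0.895
importance weights: {'clinical_score': 0.708, 'protein_score': 0.678,
                     'mutation_score': 0.635, 'methylation_score': 0.701}
```

The integrated out-of-fold AUC (0.895) exceeds every component — the
stacking gain the integrator exists for — and the importance weights
order the platforms by their standalone informativeness.

A shell workflow is available through the thin `noduleomics` CLI
(`simulate`, `build-mcb`, `mutfeat`, `select`, `train`, `score`,
`integrate`, `evaluate`, `power`); `score` and `evaluate` apply frozen
discovery artifacts and never refit, enforcing the discovery/validation
separation at the artifact level.

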