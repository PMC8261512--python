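# Versioned default study conditions for the synthetic cohort generator.
# Group parameters emulate the discovery-cohort demographics and the
# reported per-platform signal scales; see docs/methods.md for rationale.
version: 1
cohort:
  n_benign: 28
  n_malignant: 70
clinical:
  age: {benign: [51.8, 8.0], malignant: [58.7, 8.1]}
  gender_male: {benign: 0.571, malignant: 0.557}
  smoker: {benign: 0.393, malignant: 0.429}
  drinker: {benign: 0.071, malignant: 0.186}
  family_cancer_history: {benign: 0.107, malignant: 0.243}
  nodule_solid: {benign: 0.857, malignant: 0.743}
  nodule_length_cm: {benign: [1.71, 0.62], malignant: [2.06, 0.58]}
  nodule_width_cm: {benign: [1.34, 0.53], malignant: [1.67, 0.53]}
protein:
  sigma_log: 0.8
  markers:   # log-scale location (benign) and malignant shift, in log units
    CA125:    {log_median: 2.6, shift: 0.0}
    CA15_3:   {log_median: 2.4, shift: 0.0}
    CEA:      {log_median: 0.7, shift: 0.66}
    CYFRA21_1: {log_median: 0.9, shift: 0.55}
    NSE:      {log_median: 2.4, shift: 0.0}
    PROGRP:   {log_median: 3.5, shift: 0.0}
    SCC:      {log_median: 0.3, shift: 0.50}
    SF:       {log_median: 4.7, shift: 0.0}
mutation:
  # per-level Poisson call rates; near-equal between groups so the
  # mutation platform sits near chance while the cohort median count ~13
  rates:
    benign:    {1: 0.3, 2: 0.5, 3: 3.2, 4: 8.5}
    malignant: {1: 0.5, 2: 0.6, 3: 3.4, 4: 9.0}
  # per-level Beta(a, b) VAF distributions; near-identical between groups
  # (low-VAF plasma calls carry little malignancy signal on their own)
  vaf:
    benign:    {1: [1.2, 75], 2: [1.2, 75], 3: [1.2, 75], 4: [1.2, 75]}
    malignant: {1: [1.3, 70], 2: [1.3, 70], 3: [1.2, 75], 4: [1.2, 75]}
methylation:
  delta_beta: 0.2            # planted mean-beta group shift in discriminative blocks
  frac_discriminative: 0.25
  latent_sd: 1.0             # shared within-block level per sample (logit scale)
  noise_sd: 0.10             # per-site noise (logit scale); true adjacent r ~ 0.99,
                             # calibrated so sample r stays above the 0.9 MCB link
                             # rule in both groups at discovery group sizes
  depth_log_mean: 6.2        # lognormal read depth, median ~ 500x
  depth_log_sd: 0.3
  baseline_beta_range: [0.2, 0.6]
  shed_prob: 0.85            # fraction of malignant samples with detectable ctDNA
  signal_cv: 0.5             # tumor-signal magnitude dispersion (Gamma CV)
panel:
  n_blocks: 40
  sites_per_block: 5
  intra_block_gap: 50
  inter_block_gap: 1000
  chrom_name: chr1
platform_scores:
  # latent separations of the four complementary platform scores
  # (clinical, protein, mutation, methylation); AUC ~ Phi(d / sqrt 2)
  separations: {clinical: 0.95, protein: 0.8, mutation: 0.3, methylation: 1.3}
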