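"""Generator behavior: group structure, value ranges, seeded determinism."""

import numpy as np
import pandas as pd
import pytest

from noduleomics.mutations import classify_mutation_levels
from noduleomics.selection import univariate_auc
from noduleomics.synthetic import (CohortSpec, PanelSpec, generate_clinical,
                                   generate_methylation, generate_mutations,
                                   generate_platform_scores, generate_proteins)


def test_invalid_group_sizes_rejected():
    with pytest.raises(ValueError):
        CohortSpec.default(seed=0, n_benign=0)
    with pytest.raises(ValueError):
        CohortSpec.default(seed=0, n_malignant=-5)


def test_invalid_methylation_spec_rejected():
    spec = CohortSpec.default(seed=0)
    bad = dict(spec.methylation_spec, delta_beta=1.5)
    with pytest.raises(ValueError):
        CohortSpec(n_benign=5, n_malignant=5, seed=0, methylation_spec=bad)


def test_panel_gap_constraint():
    with pytest.raises(ValueError):
        PanelSpec(intra_block_gap=150, inter_block_gap=200)
    with pytest.raises(ValueError):
        PanelSpec(sites_per_block=2)


def test_clinical_age_gap_matches_group_means():
    # group means 51.8 vs 58.7 -> expected gap 6.9 years
    spec = CohortSpec.default(seed=3, n_benign=1000, n_malignant=1000)
    clin, lab = generate_clinical(spec)
    gap = clin.loc[lab == "malignant", "age"].mean() - clin.loc[lab == "benign", "age"].mean()
    assert abs(gap - 6.9) < 1.0
    assert (lab == "benign").sum() == 1000 and (lab == "malignant").sum() == 1000
    assert set(clin["gender_male"].unique()) <= {0, 1}


def test_generators_are_deterministic_under_seed():
    spec = CohortSpec.default(seed=11, n_benign=10, n_malignant=10)
    for gen in (generate_clinical, generate_proteins, generate_mutations):
        a, b = gen(spec), gen(spec)
        if isinstance(a, tuple):
            for x, y in zip(a, b):
                pd.testing.assert_frame_equal(pd.DataFrame(x), pd.DataFrame(y))
        else:
            pd.testing.assert_frame_equal(pd.DataFrame(a), pd.DataFrame(b))
    m1, _ = generate_methylation(spec)
    m2, _ = generate_methylation(spec)
    pd.testing.assert_frame_equal(m1, m2)


def test_protein_markers_positive_and_shifted_aucs():
    spec = CohortSpec.default(seed=2, n_benign=500, n_malignant=500)
    prot = generate_proteins(spec)
    lab = spec.labels()
    assert (prot > 0).all().all()
    shifted = [m for m, p in spec.protein_effects["markers"].items() if p["shift"] > 0]
    assert len(shifted) == 3
    for m in shifted:
        assert 0.6 <= univariate_auc(prot[m], lab) <= 0.8
    null = [m for m, p in spec.protein_effects["markers"].items() if p["shift"] == 0]
    for m in null:
        assert abs(univariate_auc(prot[m], lab) - 0.5) < 0.06


def test_zero_shift_proteins_are_uninformative():
    spec = CohortSpec.default(seed=4, n_benign=300, n_malignant=300)
    eff = {"sigma_log": 0.8,
           "markers": {k: dict(v, shift=0.0)
                       for k, v in spec.protein_effects["markers"].items()}}
    spec = CohortSpec(n_benign=300, n_malignant=300, seed=4, protein_effects=eff)
    prot = generate_proteins(spec)
    for m in prot.columns:
        assert abs(univariate_auc(prot[m], spec.labels()) - 0.5) < 0.07


def test_mutation_counts_and_round_trip():
    spec = CohortSpec.default(seed=5)
    calls = generate_mutations(spec)
    per_sample = calls.groupby("sample_id").size().reindex(spec.sample_ids(),
                                                           fill_value=0)
    assert 8 <= per_sample.median() <= 20
    assert (classify_mutation_levels(calls) == calls["true_level"]).all()


def test_zero_mutation_rates_give_empty_lists():
    spec = CohortSpec.default(seed=0, n_benign=5, n_malignant=5)
    ms = dict(spec.mutation_spec)
    ms["rates"] = {g: {k: 0.0 for k in (1, 2, 3, 4)} for g in ("benign", "malignant")}
    calls = generate_mutations(CohortSpec(n_benign=5, n_malignant=5, seed=0,
                                          mutation_spec=ms))
    assert len(calls) == 0


def test_methylation_beta_bounds_and_counts():
    spec = CohortSpec.default(seed=6, n_benign=20, n_malignant=20)
    meas, block_map = generate_methylation(spec)
    assert meas["beta"].between(0, 1).all()
    assert (meas["methylated_reads"] <= meas["depth"]).all()
    panel = PanelSpec.default()
    assert len(block_map) == panel.n_blocks
    assert len(meas) == spec.n_total * panel.n_blocks * panel.sites_per_block


def test_within_block_adjacent_correlation_high():
    # at n=100/group the generated within-block adjacent-site Pearson r
    # stays above the 0.9 MCB link threshold in each group
    spec = CohortSpec.default(seed=7, n_benign=100, n_malignant=100)
    meas, block_map = generate_methylation(spec)
    lab = spec.labels()
    wide = meas.pivot_table(index="sample_id", columns=["chrom", "pos"],
                            values="beta").sort_index(axis=1)
    rmin = 1.0
    for row in block_map.itertuples():
        posns = [int(x) for x in row.positions.split(",")]
        for a, b in zip(posns[:-1], posns[1:]):
            for g in ("benign", "malignant"):
                sub = wide.loc[lab == g]
                r = np.corrcoef(sub[(row.chrom, a)], sub[(row.chrom, b)])[0, 1]
                rmin = min(rmin, r)
    assert rmin >= 0.9


def test_null_cohort_has_no_differential_blocks():
    # delta-beta = 0: block-level two-sample t at p < 0.001 only by chance
    spec = CohortSpec.default(seed=8, n_benign=50, n_malignant=50)
    ms = dict(spec.methylation_spec, delta_beta=0.0)
    spec = CohortSpec(n_benign=50, n_malignant=50, seed=8, methylation_spec=ms)
    meas, block_map = generate_methylation(spec)
    lab = spec.labels()
    wide = meas.pivot_table(index="sample_id", columns=["chrom", "pos"],
                            values="beta").sort_index(axis=1)
    from scipy.stats import ttest_ind
    hits = 0
    for row in block_map.itertuples():
        posns = [(row.chrom, int(x)) for x in row.positions.split(",")]
        level = wide[posns].mean(axis=1)
        p = ttest_ind(level[lab == "benign"], level[lab == "malignant"]).pvalue
        hits += p < 0.001
    assert hits <= 1


def test_planted_block_effect_size_recovered(cohort0, mcb_chain):
    # MCB-level group difference in discriminative blocks ~ planted delta
    spec = CohortSpec.default(seed=9, n_benign=100, n_malignant=100)
    meas, block_map = generate_methylation(spec)
    lab = spec.labels()
    wide = meas.pivot_table(index="sample_id", columns=["chrom", "pos"],
                            values="beta").sort_index(axis=1)
    diffs = []
    for row in block_map[block_map["discriminative"]].itertuples():
        posns = [(row.chrom, int(x)) for x in row.positions.split(",")]
        level = wide[posns].mean(axis=1)
        diffs.append(level[lab == "malignant"].mean() - level[lab == "benign"].mean())
    delta = spec.methylation_spec["delta_beta"]
    assert abs(np.mean(diffs) - delta) < 0.04


def test_platform_scores_complementary_and_ranked():
    scores, lab = generate_platform_scores(seed=12, n_benign=300, n_malignant=300)
    assert scores.to_numpy().min() >= 0 and scores.to_numpy().max() <= 1
    aucs = {c: univariate_auc(scores[c], lab) for c in scores.columns}
    assert aucs["methylation_score"] > aucs["protein_score"]
    assert aucs["protein_score"] > aucs["mutation_score"]
    assert aucs["mutation_score"] < 0.65  # near chance
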