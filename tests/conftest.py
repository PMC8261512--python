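import numpy as np
import pandas as pd
import pytest

from noduleomics import mcb as mcb_mod
from noduleomics.selection import screen_features
from noduleomics.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def cohort0():
    """One default discovery-sized cohort (28 benign / 70 malignant), seed 0."""
    spec = CohortSpec.default(seed=0)
    data = generate_cohort(spec)
    data["spec"] = spec
    return data


@pytest.fixture(scope="session")
def mcb_chain(cohort0):
    """QC -> beta matrix -> MCB segmentation -> block matrix on cohort0."""
    lab = cohort0["labels"]
    filt = mcb_mod.qc_filter_measurements(cohort0["methylation"])
    wide = mcb_mod.beta_matrix_from_measurements(filt)
    sites = pd.DataFrame(list(wide.columns), columns=["chrom", "pos"])
    blocks = mcb_mod.build_mcbs(sites, wide[lab == "benign"], wide[lab == "malignant"])
    matrix = mcb_mod.mcb_methylation_matrix(wide, blocks)
    return {"wide": wide, "sites": sites, "blocks": blocks, "matrix": matrix,
            "labels": lab.reindex(matrix.index)}


@pytest.fixture(scope="session")
def screened0(mcb_chain):
    return screen_features(mcb_chain["matrix"], mcb_chain["labels"])


def brute_force_mcbs(sites, beta_benign, beta_malignant, criteria):
    """Independent oracle: enumerate every contiguous site run, keep those
    whose every adjacent pair qualifies (gap + per-group Pearson r), and
    report the maximal ones."""
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    n = len(sites)

    def linked(i):
        if chrom[i] != chrom[i + 1] or pos[i + 1] - pos[i] > criteria.max_gap:
            return False
        for mat in (np.asarray(beta_benign, float), np.asarray(beta_malignant, float)):
            a, b = mat[:, i], mat[:, i + 1]
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() < criteria.min_complete_pairs:
                return False
            a, b = a[ok], b[ok]
            if a.std() == 0 or b.std() == 0:
                return False
            if np.corrcoef(a, b)[0, 1] < criteria.min_r:
                return False
        return True

    link = [linked(i) for i in range(n - 1)]
    runs = []
    for i in range(n):
        for j in range(i + criteria.min_sites - 1, n):
            if all(link[k] for k in range(i, j)):
                left_ext = i > 0 and link[i - 1]
                right_ext = j < n - 1 and link[j]
                if not left_ext and not right_ext:
                    runs.append((str(chrom[i]), tuple(int(p) for p in pos[i:j + 1])))
    return sorted(set(runs))
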