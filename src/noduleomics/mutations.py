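"""Somatic-mutation functional levels and per-sample feature aggregation.

Calls are binned into four functional levels:

  L1  oncogene variant present in the core hotspot list
  L2  tumor-suppressor variant in the hotspot list, or any other
      predicted-deleterious tumor-suppressor variant
  L3  remaining exonic nonsynonymous variants
  L4  everything else

and each sample is summarized by eight numbers: per-level call count and
per-level maximal variant allele frequency (0 for an empty level).
Hotspot membership and deleteriousness arrive as input annotations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MutationCall",
    "GENE_ROLES",
    "CONSEQUENCES",
    "FEATURE_COLUMNS",
    "classify_mutation_level",
    "classify_mutation_levels",
    "aggregate_mutation_features",
    "mutation_feature_matrix",
]

GENE_ROLES = ("oncogene", "tumor_suppressor", "other")
CONSEQUENCES = ("exonic_nonsynonymous", "inframe_indel", "synonymous",
                "noncoding", "other")
LEVELS = (1, 2, 3, 4)
FEATURE_COLUMNS = [f"count_L{k}" for k in LEVELS] + [f"maxvaf_L{k}" for k in LEVELS]

CALL_COLUMNS = ["sample_id", "gene", "gene_role", "hotspot_match",
                "consequence", "deleterious", "vaf"]


@dataclass(frozen=True)
class MutationCall:
    sample_id: str
    gene: str
    gene_role: str
    hotspot_match: bool
    consequence: str
    deleterious: bool
    vaf: float

    def __post_init__(self):
        if self.gene_role not in GENE_ROLES:
            raise ValueError(f"unknown gene_role {self.gene_role!r}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if not (0 <= self.vaf <= 1):
            raise ValueError(
                f"vaf must be a fraction in [0,1], got {self.vaf} "
                "(percent-formatted input is rejected, not rescaled)")


def classify_mutation_level(call: MutationCall) -> int:
    """Functional level of one call; first matching rule wins (L1→L4)."""
    if call.gene_role == "oncogene" and call.hotspot_match:
        return 1
    if call.gene_role == "tumor_suppressor" and (call.hotspot_match or call.deleterious):
        return 2
    if call.consequence == "exonic_nonsynonymous":
        return 3
    return 4


def _validate_calls(calls: pd.DataFrame) -> None:
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    bad = calls.index[(calls["vaf"] < 0) | (calls["vaf"] > 1)].tolist()
    if bad:
        raise ValueError(f"vaf outside [0,1] at rows {bad[:20]} "
                         "(percent-formatted input is rejected)")
    bad_role = set(calls["gene_role"]) - set(GENE_ROLES)
    if bad_role:
        raise ValueError(f"unknown gene_role values: {sorted(bad_role)}")
    bad_csq = set(calls["consequence"]) - set(CONSEQUENCES)
    if bad_csq:
        raise ValueError(f"unknown consequence values: {sorted(bad_csq)}")


def classify_mutation_levels(calls: pd.DataFrame) -> pd.Series:
    """Vectorized level assignment for a call table."""
    _validate_calls(calls)
    level = np.full(len(calls), 4, dtype=int)
    exonic = (calls["consequence"] == "exonic_nonsynonymous").to_numpy()
    level[exonic] = 3
    l2 = ((calls["gene_role"] == "tumor_suppressor")
          & (calls["hotspot_match"] | calls["deleterious"])).to_numpy()
    level[l2] = 2
    l1 = ((calls["gene_role"] == "oncogene") & calls["hotspot_match"]).to_numpy()
    level[l1] = 1
    return pd.Series(level, index=calls.index, name="level")


def aggregate_mutation_features(calls: pd.DataFrame | list[MutationCall]) -> pd.Series:
    """Eight-number feature vector for one sample's calls.

    count_Lk = number of level-k calls; maxvaf_Lk = max VAF at level k,
    0 when the level is empty (a dense convention: VAF 0 means no tumor
    signal, which keeps downstream z-scoring well defined).
    """
    if isinstance(calls, list):
        calls = pd.DataFrame([vars(c) for c in calls], columns=CALL_COLUMNS)
    if len(calls) == 0:
        return pd.Series(0.0, index=FEATURE_COLUMNS)
    if calls["sample_id"].nunique() > 1:
        raise ValueError("aggregate_mutation_features expects a single sample's calls")
    levels = classify_mutation_levels(calls)
    out = {}
    for k in LEVELS:
        sub = calls.loc[levels == k, "vaf"]
        out[f"count_L{k}"] = float(len(sub))
        out[f"maxvaf_L{k}"] = float(sub.max()) if len(sub) else 0.0
    return pd.Series(out, index=FEATURE_COLUMNS)


def mutation_feature_matrix(calls: pd.DataFrame,
                            sample_ids=None) -> pd.DataFrame:
    """Samples x 8 feature table from a multi-sample call table.

    ``sample_ids`` (optional) fixes the output rows so samples with no
    calls still appear with an all-zero vector.
    """
    if len(calls):
        _validate_calls(calls)
    ids = list(sample_ids) if sample_ids is not None else sorted(calls["sample_id"].unique())
    rows = {}
    for sid in ids:
        sub = calls.loc[calls["sample_id"] == sid] if len(calls) else calls
        rows[sid] = aggregate_mutation_features(sub)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=FEATURE_COLUMNS)
    out.index.name = "sample_id"
    return out
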