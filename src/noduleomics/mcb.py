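"""Methylation-correlated block (MCB) construction.

A block is a maximal run of >= ``min_sites`` CpG sites on one chromosome in
which every adjacent pair is <= ``max_gap`` bp apart and has Pearson
correlation >= ``min_r`` across samples in the benign group AND in the
malignant group separately. Each block's per-sample methylation level is
the mean beta of its member sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MCBCriteria",
    "MCB",
    "qc_filter_measurements",
    "beta_matrix_from_measurements",
    "build_mcbs",
    "mcb_methylation_matrix",
]

CPG_COLUMNS = ["sample_id", "chrom", "pos", "beta", "depth", "methylated_reads"]


@dataclass(frozen=True)
class MCBCriteria:
    min_sites: int = 3
    max_gap: int = 100
    min_r: float = 0.9
    min_complete_pairs: int = 3  # fewer complete sample pairs -> r undefined, no link

    def __post_init__(self):
        if self.min_sites < 2:
            raise ValueError("min_sites must be >= 2")
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")
        if not (0 < self.min_r <= 1):
            raise ValueError("min_r must lie in (0, 1]")


@dataclass(frozen=True)
class MCB:
    chrom: str
    start: int  # 1-based, first member site
    end: int    # 1-based, last member site (inclusive)
    member_positions: tuple[int, ...]
    id: str

    @property
    def n_sites(self) -> int:
        return len(self.member_positions)


def validate_cpg_table(df: pd.DataFrame) -> None:
    """Raise with offending row numbers on malformed CpG measurements."""
    missing = [c for c in CPG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CpG table missing columns: {missing}")
    bad_beta = df.index[(df["beta"] < 0) | (df["beta"] > 1)].tolist()
    if bad_beta:
        raise ValueError(f"beta outside [0,1] at rows {bad_beta[:20]}")
    bad_reads = df.index[df["methylated_reads"] > df["depth"]].tolist()
    if bad_reads:
        raise ValueError(f"methylated_reads > depth at rows {bad_reads[:20]}")
    bad_depth = df.index[df["depth"] < 0].tolist()
    if bad_depth:
        raise ValueError(f"negative depth at rows {bad_depth[:20]}")


def qc_filter_measurements(measurements: pd.DataFrame, min_depth: int = 100,
                           min_meth_reads: int = 2) -> pd.DataFrame:
    """Depth / methylated-read QC on a long CpG table.

    Rows with depth < min_depth are removed; surviving rows with fewer than
    min_meth_reads supporting methylated reads keep the row but have beta
    replaced by 0. Thresholds are strict '<' on both rules.
    """
    validate_cpg_table(measurements)
    out = measurements.loc[measurements["depth"] >= min_depth].copy()
    low = out["methylated_reads"] < min_meth_reads
    out.loc[low, "beta"] = 0.0
    return out.reset_index(drop=True)


def beta_matrix_from_measurements(measurements: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long CpG table to samples x sites; columns are (chrom, pos),
    sorted by coordinate. Sites a sample lacks (e.g. removed by QC) are NaN."""
    wide = measurements.pivot_table(index="sample_id", columns=["chrom", "pos"],
                                    values="beta", aggfunc="first")
    return wide.sort_index(axis=1)


def _pairwise_r(x: np.ndarray, y: np.ndarray, min_pairs: int) -> float:
    """Pearson r over pairwise-complete entries; NaN if undefined."""
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < min_pairs:
        return np.nan
    x, y = x[ok], y[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def adjacent_links(sites: pd.DataFrame, beta_benign: np.ndarray,
                   beta_malignant: np.ndarray, criteria: MCBCriteria) -> np.ndarray:
    """Boolean vector: link between site i and i+1 (same chrom, gap <= max_gap,
    r >= min_r in both groups on pairwise-complete samples)."""
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    n = len(sites)
    links = np.zeros(max(n - 1, 0), dtype=bool)
    for i in range(n - 1):
        if chrom[i] != chrom[i + 1]:
            continue
        if pos[i + 1] - pos[i] > criteria.max_gap:
            continue
        rb = _pairwise_r(beta_benign[:, i], beta_benign[:, i + 1],
                         criteria.min_complete_pairs)
        rm = _pairwise_r(beta_malignant[:, i], beta_malignant[:, i + 1],
                         criteria.min_complete_pairs)
        if np.isnan(rb) or np.isnan(rm):
            logger.info("undefined correlation for pair %s:%d-%d; no link",
                        chrom[i], pos[i], pos[i + 1])
            continue
        links[i] = rb >= criteria.min_r and rm >= criteria.min_r
    return links


def build_mcbs(sites: pd.DataFrame, beta_benign, beta_malignant,
               criteria: MCBCriteria = MCBCriteria()) -> list[MCB]:
    """Segment sites into MCBs.

    ``sites`` has columns chrom, pos sorted by (chrom, pos); the two beta
    matrices are samples x sites arrays (or DataFrames) whose columns align
    with ``sites`` rows. Blocks are the maximal runs of linked sites with at
    least ``min_sites`` members; ids are assigned in coordinate order.
    """
    sites = sites.reset_index(drop=True)
    order = pd.MultiIndex.from_frame(sites[["chrom", "pos"]])
    if not order.is_monotonic_increasing:
        raise ValueError("sites must be sorted by (chrom, pos)")
    if sites.duplicated(["chrom", "pos"]).any():
        raise ValueError("duplicate site coordinates")
    bb = np.asarray(beta_benign, dtype=float)
    bm = np.asarray(beta_malignant, dtype=float)
    if bb.shape[1] != len(sites) or bm.shape[1] != len(sites):
        raise ValueError("beta matrices must have one column per site")

    links = adjacent_links(sites, bb, bm, criteria)
    mcbs: list[MCB] = []
    n = len(sites)
    i = 0
    while i < n:
        j = i
        while j < n - 1 and links[j]:
            j += 1
        if j - i + 1 >= criteria.min_sites:
            members = tuple(int(p) for p in sites["pos"].iloc[i:j + 1])
            mcbs.append(MCB(chrom=str(sites["chrom"].iloc[i]), start=members[0],
                            end=members[-1], member_positions=members,
                            id=f"MCB_{len(mcbs) + 1:05d}"))
        i = j + 1
    logger.info("built %d MCBs covering %d CpG sites", len(mcbs),
                sum(m.n_sites for m in mcbs))
    return mcbs


def mcb_methylation_matrix(beta_matrix: pd.DataFrame, mcbs: list[MCB]) -> pd.DataFrame:
    """Samples x MCBs table of mean member-site beta.

    ``beta_matrix`` columns are (chrom, pos). Missing member values are
    excluded from the mean; an all-missing (sample, block) entry stays NaN.
    """
    cols = {}
    for m in mcbs:
        keys = [(m.chrom, p) for p in m.member_positions]
        missing = [k for k in keys if k not in beta_matrix.columns]
        if missing:
            raise ValueError(f"MCB {m.id} references unknown sites: {missing[:5]}")
        cols[m.id] = beta_matrix[keys].mean(axis=1, skipna=True)
    out = pd.DataFrame(cols, index=beta_matrix.index)
    out.index.name = "sample_id"
    return out
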