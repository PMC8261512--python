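"""Interchange formats and run configuration.

CpG measurements and mutation calls travel as TSV, feature tables and
scores as CSV, MCBs additionally as BED (0-based half-open), model and
integrator parameters as JSON. Coordinates are 1-based in memory and in
TSV; only the BED export converts. All writers use a fixed float format so
reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mcb import MCB, validate_cpg_table
from .mutations import CALL_COLUMNS, _validate_calls

__all__ = [
    "read_cpg_table",
    "write_cpg_table",
    "read_mutation_table",
    "write_mutation_table",
    "read_feature_table",
    "write_feature_table",
    "write_mcb_bed",
    "read_mcb_bed",
    "mutation_calls_from_vcf",
    "RunConfig",
    "config_hash",
]

FLOAT_FORMAT = "%.10g"
LABELS = ("benign", "malignant")


def read_cpg_table(path) -> pd.DataFrame:
    """Validated long CpG table (sample_id, chrom, pos, beta, depth,
    methylated_reads); positions 1-based. Errors name offending rows."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    validate_cpg_table(df)
    return df


def write_cpg_table(df: pd.DataFrame, path) -> None:
    validate_cpg_table(df)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_mutation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str})
    for col in ("hotspot_match", "deleterious"):
        if col in df.columns and df[col].dtype != bool:
            df[col] = df[col].astype(bool)
    _validate_calls(df)
    return df


def write_mutation_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_feature_table(path, label_column: str | None = "label"
                       ) -> tuple[pd.DataFrame, pd.Series | None]:
    """CSV feature table keyed by sample_id; optional label column mapped to
    benign/malignant. 'NA' cells stay missing for downstream imputation."""
    df = pd.read_csv(path, index_col="sample_id", na_values=["NA", ""])
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    labels = None
    if label_column and label_column in df.columns:
        labels = df.pop(label_column).astype(str)
        bad = sorted(set(labels) - set(LABELS))
        if bad:
            raise ValueError(f"unmappable label values: {bad}")
        labels.name = "label"
    feats = df.apply(pd.to_numeric, errors="raise")
    return feats, labels


def write_feature_table(df: pd.DataFrame, path, labels: pd.Series | None = None) -> None:
    out = df.copy()
    if labels is not None:
        out.insert(0, "label", labels.reindex(out.index))
    out.to_csv(path, float_format=FLOAT_FORMAT, index_label="sample_id")


def write_mcb_bed(mcbs: list[MCB], path) -> None:
    """BED export: chrom, start-1 (0-based half-open), end, id, n_sites."""
    with open(path, "w") as fh:
        for m in mcbs:
            fh.write(f"{m.chrom}\t{m.start - 1}\t{m.end}\t{m.id}\t{m.n_sites}\n")


def read_mcb_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start0", "end", "id", "n_sites"])
    return df


def mutation_calls_from_vcf(path) -> pd.DataFrame:
    """Minimal VCF-to-table converter.

    Expects per-record INFO tags SAMPLE, GENE, ROLE, HOTSPOT (0/1),
    CSQCLASS, DELET (0/1), VAF; anything richer (genotypes, multi-allelic
    handling) is out of scope.
    """
    from cyvcf2 import VCF  # optional dependency path

    rows = []
    for rec in VCF(str(path)):
        info = dict(rec.INFO)
        rows.append({
            "sample_id": str(info["SAMPLE"]),
            "gene": str(info["GENE"]),
            "gene_role": str(info["ROLE"]),
            "hotspot_match": bool(int(info["HOTSPOT"])),
            "consequence": str(info["CSQCLASS"]),
            "deleterious": bool(int(info["DELET"])),
            "vaf": float(info["VAF"]),
        })
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    _validate_calls(df)
    return df


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Paths + per-stage parameters for a two-phase discovery/validation run.

    Validation-phase commands must reference a discovery artifact bundle
    (frozen preprocessors, features, models, cutoffs) and never fit.
    """

    role: str = "discovery"
    seed: int = 0
    outdir: str = "results"
    inputs: dict = field(default_factory=dict)
    mcb: dict = field(default_factory=dict)
    selection: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    rfecv: dict = field(default_factory=dict)
    power: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.role not in ("discovery", "validation"):
            raise ValueError("role must be 'discovery' or 'validation'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self) -> str:
        d = {k: getattr(self, k) for k in
             ("role", "seed", "outdir", "inputs", "mcb", "selection",
              "model", "rfecv", "power")}
        return yaml.safe_dump(d, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.to_yaml().encode()).hexdigest()[:12]


def write_run_log(outdir, stage: str, config: RunConfig | None = None,
                  **params) -> Path:
    """Plain-text log with seed and parameter echo (no wall-clock content,
    so identical runs produce identical logs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = [f"stage: {stage}"]
    if config is not None:
        lines += [f"config_hash: {config_hash(config)}", f"seed: {config.seed}"]
    lines += [f"{k}: {v}" for k, v in sorted(params.items())]
    path = outdir / f"{stage}.log"
    path.write_text("\n".join(lines) + "\n")
    return path
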