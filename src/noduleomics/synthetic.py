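"""Synthetic two-group nodule cohorts with the statistical structure the
downstream analysis assumes.

Four generators (clinical table, protein markers, somatic mutation call
lists, CpG-level methylation with planted correlated blocks) are pure
functions of a :class:`CohortSpec` and its seed, so every pipeline stage is
testable without any external download. Simulation starts at called beta
values and annotated mutation calls; no read-level data is produced.

The methylation model is a logit-normal latent-factor construction: each
(sample, block) draws a shared latent level, each site adds independent
logit-scale noise, which yields tunable adjacent-site correlation with
valid beta support. A planted subset of blocks carries a group mean-beta
shift delta, scaled per malignant sample by a tumor-signal factor
(Bernoulli shedding x Gamma magnitude, mean 1) to emulate ctDNA shedding
heterogeneity — this is what keeps the multivariate methylation signal
realistic instead of saturating as planted blocks accumulate.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .mutations import CALL_COLUMNS

__all__ = [
    "CohortSpec",
    "PanelSpec",
    "default_parameters",
    "generate_clinical",
    "generate_proteins",
    "generate_mutations",
    "generate_methylation",
    "generate_platform_scores",
    "generate_cohort",
]

BINARY_CLINICAL = ("gender_male", "smoker", "drinker",
                   "family_cancer_history", "nodule_solid")


def default_parameters() -> dict:
    """The versioned default study conditions (bundled YAML)."""
    ref = importlib.resources.files("noduleomics") / "defaults.yaml"
    return yaml.safe_load(ref.read_text())


def _gene_table() -> pd.DataFrame:
    ref = importlib.resources.files("noduleomics") / "data" / "gene_annotations.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


@dataclass(frozen=True)
class PanelSpec:
    """Geometry of the simulated CpG panel; the gap constants are chosen so
    ground-truth blocks are recoverable by the <=100 bp MCB distance rule."""

    n_blocks: int = 40
    sites_per_block: int = 5
    intra_block_gap: int = 50
    inter_block_gap: int = 1000
    chrom_name: str = "chr1"

    def __post_init__(self):
        if self.n_blocks < 1 or self.sites_per_block < 3:
            raise ValueError("need n_blocks >= 1 and sites_per_block >= 3")
        if not (self.intra_block_gap <= 100 < self.inter_block_gap):
            raise ValueError("require intra_block_gap <= 100 < inter_block_gap")

    @classmethod
    def default(cls) -> "PanelSpec":
        return cls(**default_parameters()["panel"])


@dataclass(frozen=True)
class CohortSpec:
    n_benign: int = 28
    n_malignant: int = 70
    seed: int = 0
    clinical_effects: dict = field(default_factory=dict)
    protein_effects: dict = field(default_factory=dict)
    mutation_spec: dict = field(default_factory=dict)
    methylation_spec: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_benign <= 0 or self.n_malignant <= 0:
            raise ValueError("group sizes must be positive")
        m = self.methylation_spec
        if m:
            if not (0 <= m["delta_beta"] <= 1):
                raise ValueError("delta_beta must lie in [0,1]")
            if m["latent_sd"] <= 0 or m["noise_sd"] < 0:
                raise ValueError("latent_sd must be > 0 and noise_sd >= 0")
            if not (0 <= m["frac_discriminative"] <= 1):
                raise ValueError("frac_discriminative must lie in [0,1]")

    @classmethod
    def default(cls, seed: int = 0, n_benign: int | None = None,
                n_malignant: int | None = None) -> "CohortSpec":
        p = default_parameters()
        return cls(
            n_benign=n_benign if n_benign is not None else p["cohort"]["n_benign"],
            n_malignant=n_malignant if n_malignant is not None else p["cohort"]["n_malignant"],
            seed=seed,
            clinical_effects=p["clinical"],
            protein_effects=p["protein"],
            mutation_spec=p["mutation"],
            methylation_spec=p["methylation"],
        )

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)

    @property
    def n_total(self) -> int:
        return self.n_benign + self.n_malignant

    def sample_ids(self) -> list[str]:
        return [f"P{i + 1:04d}" for i in range(self.n_total)]

    def labels(self) -> pd.Series:
        lab = ["benign"] * self.n_benign + ["malignant"] * self.n_malignant
        return pd.Series(lab, index=self.sample_ids(), name="label")


def _rng(spec: CohortSpec, stream: int) -> np.random.Generator:
    # one fixed stream per generator keeps each a pure function of spec+seed
    return np.random.default_rng([int(spec.seed) % (2**31), stream])


# ---------------------------------------------------------------------------
# clinical


def generate_clinical(spec: CohortSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Clinical feature table (one row per patient) + pathology labels.

    Continuous features come from group-specific Gaussians, binary features
    from group-specific Bernoulli draws; two derived nodule-size features
    (length x width, mean of the two axes) are appended.
    """
    eff = spec.clinical_effects or default_parameters()["clinical"]
    rng = _rng(spec, 0)
    labels = spec.labels()
    is_mal = (labels == "malignant").to_numpy()
    n = spec.n_total
    cols = {}
    mu, sd = zip(*[eff["age"]["benign"], eff["age"]["malignant"]])
    cols["age"] = rng.normal(np.where(is_mal, mu[1], mu[0]),
                             np.where(is_mal, sd[1], sd[0]))
    for name in BINARY_CLINICAL:
        pb, pm = eff[name]["benign"], eff[name]["malignant"]
        cols[name] = (rng.random(n) < np.where(is_mal, pm, pb)).astype(int)
    for name in ("nodule_length_cm", "nodule_width_cm"):
        (mb, sb), (mm, sm) = eff[name]["benign"], eff[name]["malignant"]
        draw = rng.normal(np.where(is_mal, mm, mb), np.where(is_mal, sm, sb))
        cols[name] = np.clip(draw, 0.2, None)
    df = pd.DataFrame(cols, index=labels.index)
    df["nodule_lw_cm2"] = df["nodule_length_cm"] * df["nodule_width_cm"]
    df["nodule_mean_size_cm"] = (df["nodule_length_cm"] + df["nodule_width_cm"]) / 2
    df.index.name = "sample_id"
    return df, labels


# ---------------------------------------------------------------------------
# proteins


def generate_proteins(spec: CohortSpec) -> pd.DataFrame:
    """Eight positive log-normal serum markers; the configured malignant
    shift applies to three of them (CEA, CYFRA 21-1, SCC at defaults)."""
    eff = spec.protein_effects or default_parameters()["protein"]
    rng = _rng(spec, 1)
    is_mal = (spec.labels() == "malignant").to_numpy()
    sigma = float(eff["sigma_log"])
    cols = {}
    for marker, par in eff["markers"].items():
        loc = par["log_median"] + par["shift"] * is_mal
        cols[marker] = np.exp(rng.normal(loc, sigma))
    df = pd.DataFrame(cols, index=spec.sample_ids())
    df.index.name = "sample_id"
    return df


# ---------------------------------------------------------------------------
# mutations


def _draw_call_fields(level: int, rng: np.random.Generator,
                      genes_by_role: dict) -> dict:
    """Annotation fields consistent with the level rules (round-trips
    through classify_mutation_level by construction)."""
    if level == 1:
        return dict(gene=rng.choice(genes_by_role["oncogene"]),
                    gene_role="oncogene", hotspot_match=True,
                    consequence="exonic_nonsynonymous",
                    deleterious=bool(rng.random() < 0.5))
    if level == 2:
        hotspot = bool(rng.random() < 0.4)
        return dict(gene=rng.choice(genes_by_role["tumor_suppressor"]),
                    gene_role="tumor_suppressor", hotspot_match=hotspot,
                    consequence=str(rng.choice(
                        ["exonic_nonsynonymous", "inframe_indel"], p=[0.85, 0.15])),
                    deleterious=True if not hotspot else bool(rng.random() < 0.7))
    if level == 3:
        role = str(rng.choice(["oncogene", "other"], p=[0.5, 0.5]))
        return dict(gene=rng.choice(genes_by_role[role]), gene_role=role,
                    hotspot_match=False, consequence="exonic_nonsynonymous",
                    deleterious=bool(rng.random() < 0.3))
    return dict(gene=rng.choice(genes_by_role["other"]), gene_role="other",
                hotspot_match=False,
                consequence=str(rng.choice(["synonymous", "noncoding"], p=[0.4, 0.6])),
                deleterious=False)


def generate_mutations(spec: CohortSpec) -> pd.DataFrame:
    """Per-sample somatic call lists (long table, one row per call).

    Per-level counts are Poisson with group-specific rates; VAFs come from
    group-specific per-level Beta distributions. A ``true_level`` column
    records the generating level for round-trip checks.
    """
    par = spec.mutation_spec or default_parameters()["mutation"]
    rng = _rng(spec, 2)
    genes = _gene_table()
    genes_by_role = {r: genes.loc[genes["role"] == r, "gene"].to_numpy()
                     for r in ("oncogene", "tumor_suppressor", "other")}
    rows = []
    for sid, lab in spec.labels().items():
        for level in (1, 2, 3, 4):
            k = rng.poisson(par["rates"][lab][level])
            a, b = par["vaf"][lab][level]
            for _ in range(k):
                fields = _draw_call_fields(level, rng, genes_by_role)
                rows.append({"sample_id": sid, **fields,
                             "vaf": float(rng.beta(a, b)), "true_level": level})
    df = pd.DataFrame(rows, columns=CALL_COLUMNS + ["true_level"])
    return df


# ---------------------------------------------------------------------------
# methylation


def _logit_location_grid(total_sd: float, n_nodes: int = 40,
                         n_grid: int = 241) -> tuple[np.ndarray, np.ndarray]:
    """Grid mapping target mean beta -> logit location mu such that
    E[expit(N(mu, total_sd^2))] equals the target (Gauss-Hermite)."""
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    scale = total_sd * np.sqrt(2.0)

    def mean_beta(mu: float) -> float:
        return float(weights @ expit(mu + scale * nodes) / np.sqrt(np.pi))

    targets = np.linspace(0.005, 0.995, n_grid)
    mus = np.array([brentq(lambda m, t=t: mean_beta(m) - t, -25, 25)
                    for t in targets])
    return targets, mus


def generate_methylation(spec: CohortSpec,
                         panel: PanelSpec | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CpG-level measurement table + ground-truth block map.

    Returns ``(measurements, block_map)``: a long table with columns
    sample_id, chrom, pos, beta, depth, methylated_reads, and one row per
    planted block (id, chrom, start, end, positions, discriminative flag,
    delta_beta). Methylated-read counts are round(beta x depth), so the
    '<2 supporting methylated reads' QC rule is exercisable.
    """
    panel = panel or PanelSpec.default()
    par = spec.methylation_spec or default_parameters()["methylation"]
    rng = _rng(spec, 3)
    labels = spec.labels()
    is_mal = (labels == "malignant").to_numpy()
    n_s, n_b, spb = spec.n_total, panel.n_blocks, panel.sites_per_block

    block_span = (spb - 1) * panel.intra_block_gap
    starts = 10_000 + np.arange(n_b) * (block_span + panel.inter_block_gap)
    positions = starts[:, None] + np.arange(spb)[None, :] * panel.intra_block_gap

    n_disc = int(round(par["frac_discriminative"] * n_b))
    disc = np.zeros(n_b, dtype=bool)
    disc[rng.choice(n_b, size=n_disc, replace=False)] = True

    lo, hi = par["baseline_beta_range"]
    base = rng.uniform(lo, hi, size=n_b)

    # per-malignant-sample tumor signal, mean 1 (shedding x magnitude)
    cv = float(par["signal_cv"])
    shape = 1.0 / cv**2 if cv > 0 else None
    shed = rng.random(n_s) < par["shed_prob"]
    mag = (rng.gamma(shape, 1.0 / shape, size=n_s) if shape else np.ones(n_s))
    signal = np.where(is_mal & shed, mag / par["shed_prob"], 0.0)

    total_sd = float(np.hypot(par["latent_sd"], par["noise_sd"]))
    grid_t, grid_mu = _logit_location_grid(total_sd)

    target = base[None, :] + par["delta_beta"] * disc[None, :] * signal[:, None]
    target = np.clip(target, 0.01, 0.97)          # (samples, blocks)
    mu = np.interp(target, grid_t, grid_mu)

    latent = rng.normal(0.0, par["latent_sd"], size=(n_s, n_b))
    noise = rng.normal(0.0, par["noise_sd"], size=(n_s, n_b, spb))
    beta = expit((mu + latent)[:, :, None] + noise)  # (samples, blocks, sites)

    depth = np.exp(rng.normal(par["depth_log_mean"], par["depth_log_sd"],
                              size=(n_s, n_b, spb)))
    depth = np.maximum(1, np.round(depth)).astype(int)
    meth = np.round(beta * depth).astype(int)

    ids = np.array(spec.sample_ids())
    measurements = pd.DataFrame({
        "sample_id": np.repeat(ids, n_b * spb),
        "chrom": panel.chrom_name,
        "pos": np.tile(positions.ravel(), n_s),
        "beta": beta.reshape(n_s, -1).ravel(),
        "depth": depth.reshape(n_s, -1).ravel(),
        "methylated_reads": meth.reshape(n_s, -1).ravel(),
    })
    block_map = pd.DataFrame({
        "block_id": [f"GT_{b + 1:04d}" for b in range(n_b)],
        "chrom": panel.chrom_name,
        "start": positions[:, 0],
        "end": positions[:, -1],
        "positions": [",".join(map(str, row)) for row in positions],
        "discriminative": disc,
        "delta_beta": np.where(disc, par["delta_beta"], 0.0),
    })
    return measurements, block_map


# ---------------------------------------------------------------------------
# platform-score toy (integration-level study conditions)


def generate_platform_scores(n_benign: int = 28, n_malignant: int = 70,
                             seed: int = 0, separations: dict | None = None
                             ) -> tuple[pd.DataFrame, pd.Series]:
    """Four complementary per-platform malignancy probabilities.

    Each platform score is a logistic transform of an independent noisy
    view of the disease state with platform-specific separation d
    (single-platform AUC ~ Phi(d / sqrt 2)); the noise terms are mutually
    independent, so the platforms carry complementary information — the
    regime in which a stacking integrator should beat each component.
    """
    separations = separations or default_parameters()["platform_scores"]["separations"]
    rng = np.random.default_rng([int(seed) % (2**31), 4])
    n = n_benign + n_malignant
    y = np.r_[np.zeros(n_benign), np.ones(n_malignant)]
    ids = [f"P{i + 1:04d}" for i in range(n)]
    cols = {f"{name}_score": expit(d * y + rng.normal(0, 1, n) * 1.0 - d / 2)
            for name, d in separations.items()}
    scores = pd.DataFrame(cols, index=ids)
    scores.index.name = "sample_id"
    labels = pd.Series(np.where(y == 1, "malignant", "benign"), index=ids,
                       name="label")
    return scores, labels


def generate_cohort(spec: CohortSpec, panel: PanelSpec | None = None) -> dict:
    """All four platforms' raw tables for one cohort, keyed by stage."""
    clinical, labels = generate_clinical(spec)
    meas, block_map = generate_methylation(spec, panel)
    return {
        "labels": labels,
        "clinical": clinical,
        "proteins": generate_proteins(spec),
        "mutations": generate_mutations(spec),
        "methylation": meas,
        "block_map": block_map,
    }
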