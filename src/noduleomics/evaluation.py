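"""ROC evaluation, cutoff optimization, and one-ROC-curve study design.

The study-design piece implements the binormal one-ROC-curve sample-size
computation of Obuchowski & McClish (the model behind the PASS "One ROC
Curve" power module): the alternative AUC is mapped to a binormal
separation ``a`` (slope ``b``, default 1), the variance of the estimated
full-curve AUC is obtained by the delta method from the variances of the
binormal parameter estimates for continuous-scale data, and the smallest
per-group n satisfying the normal-theory power inequality is returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "PowerSpec",
    "SampleSizeResult",
    "EvaluationReport",
    "rank_auc",
    "roc_auc_ci",
    "delong_variance",
    "optimal_cutoff",
    "sens_spec_at",
    "roc_sample_size",
    "simulate_roc_power",
    "suvmax_classify",
    "roc_points",
]


# ---------------------------------------------------------------------------
# AUC


def _check_two_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1 if labels.dtype.kind in "biu" else labels == "malignant"
    if labels.dtype.kind not in "biu":
        known = np.isin(labels, ("benign", "malignant"))
        if not known.all():
            raise ValueError(f"unmappable labels: {np.unique(labels[~known])}")
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present")
    return pos, ~pos


def rank_auc(scores, labels) -> float:
    """AUC = P(score_mal > score_ben) + 0.5 P(tie), via the rank formula.

    Malignant is the positive class; larger score = higher risk. The raw
    orientation is reported (values below 0.5 are not flipped).
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(labels)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    ranks = rankdata(scores)  # mid-ranks handle ties as 1/2
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def delong_variance(scores, labels) -> float:
    """DeLong variance of the AUC estimate (single-curve case)."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(labels)
    x, y = scores[pos], scores[neg]
    m, n = len(x), len(y)
    # structural components V10 (per diseased), V01 (per non-diseased)
    v10 = np.array([(np.sum(xi > y) + 0.5 * np.sum(xi == y)) / n for xi in x])
    v01 = np.array([(np.sum(x > yi) + 0.5 * np.sum(x == yi)) / m for yi in y])
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def roc_auc_ci(scores, labels, method: str = "bootstrap", n_boot: int = 2000,
               seed: int | None = 0, level: float = 0.95):
    """AUC with a confidence interval.

    method 'bootstrap': stratified percentile bootstrap; 'delong': normal
    interval from the DeLong variance.
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(labels)
    auc = rank_auc(scores, np.where(pos, 1, 0))
    a = (1 - level) / 2
    if method == "delong":
        se = math.sqrt(delong_variance(scores, np.where(pos, 1, 0)))
        z = norm.ppf(1 - a)
        lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        ip, ineg = np.flatnonzero(pos), np.flatnonzero(neg)
        stats = np.empty(n_boot)
        lab = np.r_[np.ones(len(ip), int), np.zeros(len(ineg), int)]
        for b in range(n_boot):
            idx = np.r_[rng.choice(ip, len(ip)), rng.choice(ineg, len(ineg))]
            stats[b] = rank_auc(scores[idx], lab)
        lo, hi = np.quantile(stats, [a, 1 - a])
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return auc, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# cutoffs


def sens_spec_at(scores, labels, threshold: float) -> tuple[float, float]:
    """Sensitivity and specificity with the rule score > threshold => malignant."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(labels)
    pred = scores > threshold
    sens = float(pred[pos].mean())
    spec = float((~pred[neg]).mean())
    return sens, spec


def optimal_cutoff(scores, labels) -> float:
    """Threshold maximizing sensitivity + specificity (Youden-style).

    Candidates are the observed distinct values and the midpoints of
    adjacent distinct values; ties on the objective are broken toward the
    higher threshold (higher specificity).
    """
    scores = np.asarray(scores, dtype=float)
    _check_two_classes(labels)
    uniq = np.unique(scores)
    cands = np.concatenate([uniq, (uniq[:-1] + uniq[1:]) / 2]) if len(uniq) > 1 else uniq
    best_t, best_obj, best_spec = None, -np.inf, -np.inf
    for t in np.sort(cands):
        sens, spec = sens_spec_at(scores, labels, t)
        obj = sens + spec
        if obj > best_obj or (obj == best_obj and spec >= best_spec):
            best_t, best_obj, best_spec = float(t), obj, spec
    return best_t


def roc_points(scores, labels) -> np.ndarray:
    """(threshold, sensitivity, specificity) rows over all candidate cuts."""
    uniq = np.unique(np.asarray(scores, dtype=float))
    cands = np.concatenate([[uniq[0] - 1], uniq])
    return np.array([(t, *sens_spec_at(scores, labels, t)) for t in cands])


# ---------------------------------------------------------------------------
# study design


@dataclass(frozen=True)
class PowerSpec:
    """Hypotheses and operating characteristics for the one-ROC-curve test.

    allocation_ratio is benign:malignant (non-diseased per diseased).
    ``b`` is the binormal slope (sd_nondiseased / sd_diseased).
    """

    auc_alt: float
    auc_null: float = 0.5
    alpha: float = 0.05
    power: float = 0.90
    allocation_ratio: float = 1.0
    sided: str = "two"
    b: float = 1.0

    def __post_init__(self):
        if not (0.5 <= self.auc_null < self.auc_alt < 1):
            raise ValueError("require 0.5 <= auc_null < auc_alt < 1")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0,1)")
        if self.allocation_ratio <= 0 or self.b <= 0:
            raise ValueError("allocation_ratio and b must be positive")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")


@dataclass(frozen=True)
class SampleSizeResult:
    n_malignant: int
    n_benign: int
    achieved_power: float

    @property
    def n_total(self) -> int:
        return self.n_malignant + self.n_benign


def binormal_a(auc: float, b: float = 1.0) -> float:
    """Binormal separation a with slope b giving the requested full AUC."""
    return norm.ppf(auc) * math.sqrt(1 + b * b)


def _auc_variance(auc: float, b: float, ratio: float, n_dis: int) -> float:
    """Delta-method variance of the full-AUC estimate, continuous-scale data.

    Components (n_dis diseased, ratio = n_nondiseased / n_dis):
      var(a^) = (a^2 + 2 + 2 b^2/ratio) / (2 n_dis)
      var(b^) = b^2 (1 + 1/ratio) / (2 n_dis)
      cov(a^, b^) = a b / (2 n_dis)
    mapped through A = Phi(a / sqrt(1+b^2)).
    """
    a = binormal_a(auc, b)
    s2 = 1 + b * b
    f = math.exp(-a * a / (2 * s2)) / math.sqrt(2 * math.pi * s2)
    g = -a * b * math.exp(-a * a / (2 * s2)) / math.sqrt(2 * math.pi * s2**3)
    va = (a * a + 2 + 2 * b * b / ratio) / (2 * n_dis)
    vb = b * b * (1 + 1 / ratio) / (2 * n_dis)
    cab = a * b / (2 * n_dis)
    return f * f * va + g * g * vb + 2 * f * g * cab


def _power_at(spec: PowerSpec, n_dis: int) -> float:
    z = norm.ppf(1 - spec.alpha / (2 if spec.sided == "two" else 1))
    v0 = _auc_variance(max(spec.auc_null, 0.5 + 1e-12), spec.b,
                       spec.allocation_ratio, n_dis)
    v1 = _auc_variance(spec.auc_alt, spec.b, spec.allocation_ratio, n_dis)
    delta = spec.auc_alt - spec.auc_null
    return float(norm.cdf((delta - z * math.sqrt(v0)) / math.sqrt(v1)))


def roc_sample_size(spec: PowerSpec, n_max: int = 100_000) -> SampleSizeResult:
    """Smallest per-group n meeting the power requirement.

    Returns the minimal number of malignant (diseased) samples and the
    corresponding benign count n_benign = ceil(ratio * n_malignant).
    Monotone: non-increasing in auc_alt, non-decreasing in power.
    """
    for n in range(2, n_max + 1):
        p = _power_at(spec, n)
        if p >= spec.power:
            return SampleSizeResult(n_malignant=n,
                                    n_benign=math.ceil(spec.allocation_ratio * n),
                                    achieved_power=p)
    raise ValueError("no n <= n_max achieves the requested power")


def simulate_roc_power(spec: PowerSpec, n_malignant: int, n_benign: int | None = None,
                       n_reps: int = 5000, seed: int | None = 0) -> float:
    """Monte-Carlo check of the analytic power at a given design.

    Scores are drawn from the binormal model at ``auc_alt``; each replicate
    estimates the binormal AUC by plugging in group means/sds and tests it
    against ``auc_null`` with the null-variance z statistic used by the
    sample-size formula. Returns the empirical rejection rate.
    """
    rng = np.random.default_rng(seed)
    if n_benign is None:
        n_benign = math.ceil(spec.allocation_ratio * n_malignant)
    a_true = binormal_a(spec.auc_alt, spec.b)
    z_crit = norm.ppf(1 - spec.alpha / (2 if spec.sided == "two" else 1))
    ratio = n_benign / n_malignant
    x = rng.normal(a_true, 1.0, size=(n_reps, n_malignant))  # diseased
    y = rng.normal(0.0, spec.b, size=(n_reps, n_benign))     # non-diseased
    a_hat = (x.mean(1) - y.mean(1)) / x.std(1, ddof=1)
    b_hat = y.std(1, ddof=1) / x.std(1, ddof=1)
    auc_hat = norm.cdf(a_hat / np.sqrt(1 + b_hat**2))
    v0 = np.array([_auc_variance(max(spec.auc_null, 0.5 + 1e-12), b, ratio, n_malignant)
                   for b in b_hat])
    z = (auc_hat - spec.auc_null) / np.sqrt(v0)
    rej = np.abs(z) > z_crit if spec.sided == "two" else z > z_crit
    return float(rej.mean())


# ---------------------------------------------------------------------------
# reports


@dataclass
class EvaluationReport:
    """Operating summary of a continuous score against pathology labels."""

    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    predicted: np.ndarray = field(repr=False)

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1],
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def evaluate_scores(scores, labels, cutoff: float | None = None,
                    n_boot: int = 2000, seed: int | None = 0) -> EvaluationReport:
    """Full evaluation: AUC + bootstrap CI, cutoff (optimized unless given),
    sensitivity/specificity at that cutoff, per-sample predicted labels."""
    scores = np.asarray(scores, dtype=float)
    if cutoff is None:
        cutoff = optimal_cutoff(scores, labels)
    auc, ci = roc_auc_ci(scores, labels, n_boot=n_boot, seed=seed)
    sens, spec = sens_spec_at(scores, labels, cutoff)
    return EvaluationReport(auc=auc, auc_ci=ci, cutoff=cutoff,
                            sensitivity=sens, specificity=spec,
                            predicted=(scores > cutoff))


def suvmax_classify(suv_values, labels, threshold: float = 2.5,
                    n_boot: int = 2000, seed: int | None = 0) -> EvaluationReport:
    """PET/CT baseline: SUVmax > threshold (conventionally 2.5) => malignant.

    The AUC is that of the continuous SUVmax score; sensitivity/specificity
    are at the fixed conventional threshold, not an optimized one.
    """
    suv = np.asarray(suv_values, dtype=float)
    if (suv < 0).any():
        raise ValueError("SUVmax values must be non-negative")
    return evaluate_scores(suv, labels, cutoff=threshold, n_boot=n_boot, seed=seed)
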