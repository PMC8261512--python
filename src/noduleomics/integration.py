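"""Bernoulli naive-Bayes stacking of the four platform scores.

Each platform's probability score is binarized at that platform's
discovery-optimal cutoff (not a shared 0.5 — the platforms' calibrated
score scales differ), and a Bernoulli naive-Bayes layer with Laplace
smoothing combines the four votes into a posterior probability of
malignancy. Per-platform importance weights summarize how much each
platform's fitted conditionals alone say about the truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import optimal_cutoff

__all__ = [
    "IntegratorParams",
    "train_integrator",
    "predict_integrated",
    "platform_importance",
]

CLASSES = ("benign", "malignant")


@dataclass(frozen=True)
class IntegratorParams:
    platforms: tuple[str, ...]
    priors: dict              # class -> prior probability
    thresholds: dict          # platform -> binarization cutoff
    conditionals: dict        # platform -> {class: P(bin = 1 | class)}
    alpha: float

    def to_json(self) -> str:
        d = {"platforms": list(self.platforms), "priors": self.priors,
             "thresholds": self.thresholds, "conditionals": self.conditionals,
             "alpha": self.alpha}
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "IntegratorParams":
        d = json.loads(text)
        return cls(platforms=tuple(d["platforms"]), priors=d["priors"],
                   thresholds=d["thresholds"], conditionals=d["conditionals"],
                   alpha=d["alpha"])


def _check_scores(scores: pd.DataFrame, platforms) -> None:
    missing = [p for p in platforms if p not in scores.columns]
    if missing:
        raise ValueError(f"missing platform score columns: {missing}")
    sub = scores[list(platforms)]
    if ((sub < 0) | (sub > 1)).any().any():
        raise ValueError("platform scores must lie in [0,1]")


def train_integrator(scores: pd.DataFrame, labels, alpha: float = 1.0,
                     thresholds: dict | None = None) -> IntegratorParams:
    """Fit the stacking layer on discovery platform scores.

    Binarization thresholds default to each platform's sensitivity+
    specificity-optimal cutoff on the discovery scores; conditionals are
    Laplace-smoothed Bernoulli rates per class; priors are empirical class
    frequencies.
    """
    platforms = tuple(str(c) for c in scores.columns)
    _check_scores(scores, platforms)
    lab = np.asarray(labels)
    if set(np.unique(lab)) != set(CLASSES):
        raise ValueError("labels must contain both 'benign' and 'malignant'")
    if thresholds is None:
        thresholds = {p: float(optimal_cutoff(scores[p].to_numpy(), lab))
                      for p in platforms}
    priors = {c: float(np.mean(lab == c)) for c in CLASSES}
    conditionals = {}
    for p in platforms:
        binv = scores[p].to_numpy() > thresholds[p]
        conditionals[p] = {
            c: float((binv[lab == c].sum() + alpha) / ((lab == c).sum() + 2 * alpha))
            for c in CLASSES}
    return IntegratorParams(platforms=platforms, priors=priors,
                            thresholds=thresholds, conditionals=conditionals,
                            alpha=alpha)


def predict_integrated(params: IntegratorParams, scores: pd.DataFrame) -> pd.Series:
    """Posterior probability of malignancy for each sample.

    posterior(c) ∝ prior(c) · Π_platforms P(bin_k | c), normalized over the
    two classes; exact Bayes arithmetic on the fitted Bernoulli rates.
    """
    _check_scores(scores, params.platforms)
    log_post = {c: np.full(len(scores), np.log(params.priors[c])) for c in CLASSES}
    for p in params.platforms:
        binv = scores[p].to_numpy() > params.thresholds[p]
        for c in CLASSES:
            q = params.conditionals[p][c]
            log_post[c] += np.where(binv, np.log(q), np.log1p(-q))
    m = np.maximum(log_post["benign"], log_post["malignant"])
    num = np.exp(log_post["malignant"] - m)
    den = num + np.exp(log_post["benign"] - m)
    return pd.Series(num / den, index=scores.index, name="integrated_score")


def platform_importance(params: IntegratorParams, scores: pd.DataFrame,
                        labels) -> dict:
    """Mean posterior probability assigned to each sample's true class by a
    single-platform reduction of the fitted integrator.

    A perfectly informative platform approaches 1 (as smoothing vanishes);
    an uninformative platform with balanced priors sits at 0.5. This is a
    bounded, informativeness-respecting summary of the fitted conditionals,
    reported alongside the integrated model.
    """
    _check_scores(scores, params.platforms)
    lab = np.asarray(labels)
    weights = {}
    for p in params.platforms:
        binv = scores[p].to_numpy() > params.thresholds[p]
        post = {}
        for c in CLASSES:
            q = params.conditionals[p][c]
            post[c] = params.priors[c] * np.where(binv, q, 1 - q)
        total = post["benign"] + post["malignant"]
        p_true = np.where(lab == "malignant",
                          post["malignant"] / total, post["benign"] / total)
        weights[p] = float(p_true.mean())
    return weights
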