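"""Per-platform preprocessing and linear-SVM malignancy classifiers.

Preprocessing is frozen on the discovery cohort: values are mapped to
log2(x+1), missing entries are imputed with the discovery median of the
transformed feature, and features are standardized with the discovery
mean/std — validation data is transformed with the stored parameters and
never refit. Feature refinement uses repeated recursive feature
elimination with stratified shuffle-split cross-validation; classifiers
are linear-kernel SVMs with grid-searched regularization and Platt
(sigmoid) calibration of the margin, evaluated by stratified out-of-fold
prediction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.feature_selection import RFECV
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import (GridSearchCV, StratifiedKFold,
                                     StratifiedShuffleSplit)
from sklearn.svm import SVC, LinearSVC

from .evaluation import rank_auc

__all__ = [
    "PreprocessParams",
    "ModelSpec",
    "RfecvSpec",
    "PlatformModel",
    "fit_preprocessor",
    "apply_preprocessor",
    "rfecv_select",
    "train_platform_model",
    "bootstrap_auc",
]

DEFAULT_C_GRID = tuple(float(c) for c in np.logspace(-3, 3, 7))
_TRANSFORMED_FLAG = "noduleomics_preprocessed"


def _labels01(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "biu":
        y = labels.astype(int)
    else:
        y = (labels == "malignant").astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y


@dataclass(frozen=True)
class PreprocessParams:
    """Discovery-frozen transform: log2(x+1) -> median imputation -> z-score."""

    medians: pd.Series        # of log-transformed discovery values
    means: pd.Series          # of imputed, log-transformed discovery values
    stds: pd.Series
    dropped: tuple[str, ...]  # zero-variance features removed

    @property
    def features(self) -> list[str]:
        return list(self.means.index)


def fit_preprocessor(table: pd.DataFrame) -> PreprocessParams:
    """Learn the transform from a discovery feature table.

    Order is fixed: log2(x+1), then per-feature medians of the transformed
    values (the imputation constants), then mean/std of the median-imputed
    transformed table. Zero-variance features are dropped and recorded.
    """
    if (table < 0).any().any():
        bad = table.columns[(table < 0).any()].tolist()
        raise ValueError(f"negative values (log2(x+1) domain) in {bad}")
    logged = np.log2(table + 1.0)
    medians = logged.median(axis=0, skipna=True)
    imputed = logged.fillna(medians)
    means = imputed.mean(axis=0)
    stds = imputed.std(axis=0, ddof=0)
    dropped = tuple(str(c) for c in table.columns[stds == 0])
    if dropped:
        warnings.warn(f"dropping zero-variance features: {dropped}")
    keep = [c for c in table.columns if c not in dropped]
    return PreprocessParams(medians=medians[keep], means=means[keep],
                            stds=stds[keep], dropped=dropped)


def apply_preprocessor(params: PreprocessParams, table: pd.DataFrame) -> pd.DataFrame:
    """Apply a discovery-frozen transform to any cohort's table.

    Missing entries become the discovery median (post-log); z-scoring uses
    the discovery mean/std. Applying twice is refused (the output is
    flagged), since a double transform would silently corrupt scales.
    """
    if table.attrs.get(_TRANSFORMED_FLAG):
        raise ValueError("table is already preprocessed; refusing to transform again")
    unseen = [c for c in table.columns if c not in params.medians.index
              and c not in params.dropped]
    if unseen:
        raise ValueError(f"columns not seen at fit time: {unseen}")
    # absent columns are allowed: they become all-missing and take the median
    sub = table.reindex(columns=params.features)
    if (sub < 0).any().any():
        raise ValueError("negative values in log2(x+1) domain")
    logged = np.log2(sub + 1.0).fillna(params.medians)
    z = (logged - params.means) / params.stds
    z.attrs[_TRANSFORMED_FLAG] = True
    return z


# ---------------------------------------------------------------------------
# RFECV consensus


@dataclass(frozen=True)
class RfecvSpec:
    n_repeats: int = 20
    splits_per_repeat: int = 10
    test_fraction_range: tuple[float, float] = (0.20, 0.40)
    seed: int = 0
    # elimination-estimator regularization: weak regularization lets the
    # max-margin solution concentrate weight on a subset of redundant
    # informative features, and RFE then discards the rest; C = 0.1 spreads
    # the weights and keeps rankings faithful to informativeness
    svm_c: float = 0.1

    def __post_init__(self):
        lo, hi = self.test_fraction_range
        if not (0 < lo <= hi < 1):
            raise ValueError("test fractions must lie in (0,1)")


def rfecv_select(table: pd.DataFrame, labels,
                 spec: RfecvSpec = RfecvSpec()) -> list[str]:
    """Consensus feature subset over repeated RFECV runs.

    Each repeat runs recursive elimination ranked by linear-SVM weights,
    validated by stratified shuffle splits at a test fraction drawn from
    the spec's range; the consensus keeps features selected in a majority
    of repeats. Deterministic under the spec seed.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 features")
    y = _labels01(labels)
    if min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 samples per class")
    rng = np.random.default_rng(spec.seed)
    votes = np.zeros(table.shape[1], dtype=int)
    X = table.to_numpy(dtype=float)
    for rep in range(spec.n_repeats):
        frac = float(rng.uniform(*spec.test_fraction_range))
        cv = StratifiedShuffleSplit(n_splits=spec.splits_per_repeat,
                                    test_size=frac,
                                    random_state=int(rng.integers(2**31)))
        est = LinearSVC(C=spec.svm_c, max_iter=20_000)
        sel = RFECV(est, step=1, cv=cv, scoring="roc_auc", min_features_to_select=1)
        sel.fit(X, y)
        votes += sel.support_.astype(int)
    keep = votes > spec.n_repeats / 2
    if not keep.any():  # degenerate (no majority feature): keep the top voted
        keep = votes == votes.max()
    return [str(c) for c in table.columns[keep]]


# ---------------------------------------------------------------------------
# platform SVM


@dataclass(frozen=True)
class ModelSpec:
    kernel: str = "linear"
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    outer_folds: int = 13
    inner_splits: int = 10
    inner_train_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.kernel != "linear":
            raise ValueError("only the linear kernel is supported")
        if self.outer_folds < 2:
            raise ValueError("outer_folds must be >= 2")
        if not (0 < self.inner_train_fraction < 1):
            raise ValueError("inner_train_fraction must lie in (0,1)")


@dataclass
class PlatformModel:
    """A fitted platform classifier: linear SVM weights + Platt calibration.

    ``oof_scores`` are the honest out-of-fold calibrated probabilities on
    the discovery cohort; ``predict_proba`` applies the refit full-cohort
    model to new (already preprocessed) data.
    """

    features: list[str]
    coef: np.ndarray
    intercept: float
    platt_a: float           # P = expit(platt_a * margin + platt_b)
    platt_b: float
    best_c: float
    oof_scores: pd.Series = field(repr=False)
    oof_auc: float = float("nan")

    def decision_function(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.features].to_numpy(dtype=float)
        return X @ self.coef + self.intercept

    def predict_proba(self, table: pd.DataFrame) -> pd.Series:
        p = expit(self.platt_a * self.decision_function(table) + self.platt_b)
        return pd.Series(p, index=table.index, name="score")

    def to_json(self) -> str:
        d = {"features": self.features, "coef": self.coef.tolist(),
             "intercept": self.intercept, "platt_a": self.platt_a,
             "platt_b": self.platt_b, "best_c": self.best_c,
             "oof_auc": self.oof_auc,
             "oof_scores": {str(k): float(v) for k, v in self.oof_scores.items()}}
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlatformModel":
        d = json.loads(text)
        oof = pd.Series(d["oof_scores"], name="score")
        return cls(features=d["features"], coef=np.asarray(d["coef"]),
                   intercept=d["intercept"], platt_a=d["platt_a"],
                   platt_b=d["platt_b"], best_c=d["best_c"],
                   oof_scores=oof, oof_auc=d["oof_auc"])


def _grid_search_c(X: np.ndarray, y: np.ndarray, spec: ModelSpec,
                   seed: int) -> float:
    """Best C by exhaustive grid search on stratified 60/40 shuffle splits."""
    cv = StratifiedShuffleSplit(n_splits=spec.inner_splits,
                                train_size=spec.inner_train_fraction,
                                test_size=round(1 - spec.inner_train_fraction, 10),
                                random_state=seed)
    gs = GridSearchCV(SVC(kernel="linear"), {"C": list(spec.c_grid)},
                      cv=cv, scoring="roc_auc", n_jobs=None)
    gs.fit(X, y)
    return float(gs.best_params_["C"])


def _platt(margins: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    lr = LogisticRegression(C=1e6, max_iter=10_000)
    lr.fit(margins.reshape(-1, 1), y)
    return float(lr.coef_[0, 0]), float(lr.intercept_[0])


def train_platform_model(table: pd.DataFrame, labels,
                         spec: ModelSpec = ModelSpec()) -> PlatformModel:
    """Train one platform's linear-SVM scorer on the discovery cohort.

    Outer stratified k-fold (13 at default) cross-validation produces
    out-of-fold probability scores for honest discovery evaluation; within
    each training part, C is grid-searched on stratified 60/40 shuffle
    splits, the SVM is refit, and a sigmoid (Platt) calibration is fitted
    on the training margins. The returned model is refit on all discovery
    samples with the full-cohort best C.
    """
    y = _labels01(labels)
    X = table.to_numpy(dtype=float)
    n_folds = min(spec.outer_folds, int(np.bincount(y).min()))
    if n_folds < spec.outer_folds:
        warnings.warn(f"reducing outer folds to {n_folds} (smallest class size)")
    if n_folds < 2:
        raise ValueError("smallest class too small for cross-validation")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=spec.seed)
    oof = np.full(len(y), np.nan)
    for i, (tr, te) in enumerate(skf.split(X, y)):
        c = _grid_search_c(X[tr], y[tr], spec, seed=spec.seed + 1000 + i)
        svc = SVC(kernel="linear", C=c).fit(X[tr], y[tr])
        a, b = _platt(svc.decision_function(X[tr]), y[tr])
        oof[te] = expit(a * svc.decision_function(X[te]) + b)
    oof_auc = rank_auc(oof, y)

    best_c = _grid_search_c(X, y, spec, seed=spec.seed + 999)
    svc = SVC(kernel="linear", C=best_c).fit(X, y)
    a, b = _platt(svc.decision_function(X), y)
    return PlatformModel(features=[str(c) for c in table.columns],
                         coef=svc.coef_.ravel().astype(float),
                         intercept=float(svc.intercept_[0]),
                         platt_a=a, platt_b=b, best_c=best_c,
                         oof_scores=pd.Series(oof, index=table.index, name="score"),
                         oof_auc=oof_auc)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_auc(scores, labels, n_boot: int = 1000, seed: int | None = 0,
                  stratified: bool = True, max_redraw: int = 100):
    """Bootstrap mean AUC and percentile 95% CI.

    Stratified resampling (default) resamples within each class, so every
    resample keeps both classes; with ``stratified=False`` single-class
    resamples are redrawn (error after ``max_redraw`` failures).
    """
    scores = np.asarray(scores, dtype=float)
    y = _labels01(labels)
    rng = np.random.default_rng(seed)
    idx_pos, idx_neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        if stratified:
            idx = np.r_[rng.choice(idx_pos, len(idx_pos)),
                        rng.choice(idx_neg, len(idx_neg))]
        else:
            for attempt in range(max_redraw + 1):
                idx = rng.choice(len(y), len(y))
                if len(np.unique(y[idx])) == 2:
                    break
            else:
                raise RuntimeError("degenerate bootstrap resamples")
        stats[b] = rank_auc(scores[idx], y[idx])
    lo, hi = np.quantile(stats, [0.025, 0.975])
    return float(stats.mean()), (float(lo), float(hi))
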