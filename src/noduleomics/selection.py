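"""Consensus univariate marker screening.

Six univariate tests are run per candidate feature (ANOVA, Fisher's exact
test, chi-square, Wilcoxon rank-sum, Mann-Whitney, Student's t); a feature
is a candidate marker when at least ``min_tests_passed`` of them reach
p < alpha (default: 4 of 6 at alpha 0.1). The Wilcoxon and Mann-Whitney
slots are the same rank statistic under two numerical conventions
(asymptotic with continuity correction vs exact/asymptotic without), so
six distinct p-values exist. Univariate AUC is reported alongside but is
not a selection criterion. No multiplicity correction is applied; the
>= 4-of-6 consensus is the guard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import rank_auc

__all__ = [
    "SelectionCriteria",
    "UnivariateResult",
    "TEST_NAMES",
    "univariate_test_suite",
    "univariate_auc",
    "screen_features",
    "consensus_select",
]

TEST_NAMES = ("anova", "fisher", "chisq", "wilcoxon", "mannwhitney", "ttest")


@dataclass(frozen=True)
class SelectionCriteria:
    alpha: float = 0.1
    min_tests_passed: int = 4
    n_tests: int = 6

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0,1)")
        if not (1 <= self.min_tests_passed <= self.n_tests):
            raise ValueError("min_tests_passed must lie in [1, n_tests]")


@dataclass(frozen=True)
class UnivariateResult:
    feature: str
    p_values: dict
    n_passed: int
    selected: bool
    auc: float


def _split(values, labels):
    values = np.asarray(values)
    labels = np.asarray(labels)
    mal = labels == ("malignant" if labels.dtype.kind not in "biu" else 1)
    x, y = values[~mal], values[mal]  # benign, malignant
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 samples per group")
    return x, y


def _contingency(values, labels, categorical: bool) -> np.ndarray:
    """2x2 (or r x 2) table; continuous features are median-dichotomized
    on the pooled sample (> pooled median vs <=)."""
    x, y = _split(values, labels)
    if categorical:
        cats = np.unique(np.concatenate([x, y]))
        return np.array([[np.sum(x == c), np.sum(y == c)] for c in cats], dtype=float)
    med = np.median(np.concatenate([x, y]))
    return np.array([[np.sum(x > med), np.sum(y > med)],
                     [np.sum(x <= med), np.sum(y <= med)]], dtype=float)


def univariate_test_suite(values, labels, categorical: bool = False) -> dict:
    """The six named p-values for one feature (all two-sided).

    Continuous inputs: ANOVA / t on the raw values, rank tests on ranks,
    Fisher and chi-square on the pooled-median 2x2 split. Categorical
    inputs: native contingency table for Fisher/chi-square, category codes
    for the remaining tests. Degenerate inputs (constant vector, empty
    table margin) yield p = 1 with a warning rather than an error.
    """
    if categorical:
        codes, _ = pd.factorize(np.asarray(values))
        num = codes.astype(float)
    else:
        num = np.asarray(values, dtype=float)
    x, y = _split(num, labels)
    p = {}

    constant = np.all(num == num[0])
    if constant:
        warnings.warn("constant feature: location tests return p = 1")
        for name in ("anova", "wilcoxon", "mannwhitney", "ttest"):
            p[name] = 1.0
    else:
        p["anova"] = float(stats.f_oneway(x, y).pvalue)
        p["ttest"] = float(stats.ttest_ind(x, y, equal_var=True).pvalue)
        # same rank statistic, two conventions => two distinct p-values
        p["wilcoxon"] = float(stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=True).pvalue)
        exact = len(x) <= 25 and len(y) <= 25
        p["mannwhitney"] = float(stats.mannwhitneyu(
            x, y, alternative="two-sided",
            method="exact" if exact else "asymptotic",
            use_continuity=False).pvalue)

    table = _contingency(num, labels, categorical)
    nonzero = table[table.sum(axis=1) > 0]
    if nonzero.shape[0] < 2 or (nonzero.sum(axis=0) == 0).any():
        warnings.warn("degenerate contingency table: Fisher/chi-square p = 1")
        p["fisher"] = 1.0
        p["chisq"] = 1.0
    else:
        if nonzero.shape == (2, 2):
            p["fisher"] = float(stats.fisher_exact(nonzero)[1])
        else:
            # scipy's Fisher test is 2x2-only; fall back to the chi-square
            # p-value for wider categorical tables
            warnings.warn("Fisher slot falls back to chi-square for r x 2 tables")
            p["fisher"] = float(stats.chi2_contingency(nonzero)[1])
        try:
            p["chisq"] = float(stats.chi2_contingency(nonzero)[1])
        except ValueError:
            p["chisq"] = 1.0
    return {name: p[name] for name in TEST_NAMES}


def univariate_auc(values, labels) -> float:
    """Rank-formula AUC with malignant positive and larger value = higher
    risk; the raw orientation is reported (may fall below 0.5)."""
    return rank_auc(np.asarray(values, dtype=float), labels)


def screen_features(table: pd.DataFrame, labels,
                    criteria: SelectionCriteria = SelectionCriteria(),
                    categorical_columns: tuple = ()) -> list[UnivariateResult]:
    """Run the six-test suite + AUC over every column of a feature table."""
    results = []
    for col in table.columns:
        cat = col in categorical_columns
        vals = table[col]
        if cat:
            codes, _ = pd.factorize(vals)
            auc = rank_auc(codes.astype(float), labels)
        else:
            auc = rank_auc(vals.to_numpy(dtype=float), labels)
        p = univariate_test_suite(vals.to_numpy(), labels, categorical=cat)
        n_passed = int(sum(v < criteria.alpha for v in p.values()))
        results.append(UnivariateResult(
            feature=str(col), p_values=p, n_passed=n_passed,
            selected=n_passed >= criteria.min_tests_passed, auc=auc))
    return results


def consensus_select(results: list[UnivariateResult],
                     criteria: SelectionCriteria = SelectionCriteria()) -> list[str]:
    """Features significant (p < alpha) in at least min_tests_passed of the
    six tests, in input order."""
    out = []
    for r in results:
        n_passed = sum(v < criteria.alpha for v in r.p_values.values())
        if n_passed >= criteria.min_tests_passed:
            out.append(r.feature)
    return out


def results_frame(results: list[UnivariateResult]) -> pd.DataFrame:
    """Flat per-feature results table (p-values, n_passed, selected, AUC)."""
    rows = []
    for r in results:
        row = {"feature": r.feature, **{f"p_{k}": v for k, v in r.p_values.items()},
               "n_passed": r.n_passed, "selected": r.selected, "auc": r.auc}
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")
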