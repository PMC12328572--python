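"""Statistical procedures of the analysis chain.

Thin, contract-checked wrappers around scipy.stats: paired t, Pearson
chi-square on 2x2 tables, Holm step-down multiplicity correction, an
Anderson-Darling normality gate routing to parametric vs nonparametric
paired comparisons, and Pearson correlation.  Every wrapper returns a
:class:`TestResult` so results tables can carry statistic/df/p columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats


@dataclass
class TestResult:
    statistic: float
    df: Optional[float]
    p: float
    adjusted_p: Optional[float] = None
    method: str = ""
    flags: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError("p outside [0, 1]")


def paired_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided paired t-test; df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("paired samples of equal length >= 2 required")
    d = x - y
    if np.allclose(d, 0.0):
        return TestResult(statistic=0.0, df=x.size - 1, p=1.0,
                          method="paired_t", flags=("identical samples",))
    if np.allclose(d, d[0]):
        return TestResult(statistic=math.nan, df=x.size - 1, p=math.nan,
                          method="paired_t", flags=("zero-variance differences",))
    res = stats.ttest_rel(x, y)
    return TestResult(statistic=float(res.statistic), df=x.size - 1,
                      p=float(res.pvalue), method="paired_t")


def wilcoxon_paired(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test (the nonparametric fallback)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("paired samples of equal length >= 2 required")
    res = stats.wilcoxon(x, y)
    return TestResult(statistic=float(res.statistic), df=None,
                      p=float(res.pvalue), method="wilcoxon")


def holm_correction(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values, in input order.

    Sort ascending, multiply the i-th smallest by (m - i), enforce
    monotonicity with a running maximum, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.maximum.accumulate(p[order] * (m - np.arange(m)))
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def chi_square_2x2(counts, continuity: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction
    by default (configurable)."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("a 2x2 table is required")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=continuity)
    return TestResult(statistic=float(chi2), df=float(df), p=float(p),
                      method="chi2_2x2")


def anderson_darling_gate(sample: Sequence[float], alpha: float = 0.05) -> str:
    """Route to 'parametric' or 'nonparametric' based on an Anderson-Darling
    normality test at the 5% level."""
    x = np.asarray(sample, dtype=float)
    if x.size < 8:
        raise ValueError("sample too small for the normality gate (n >= 8)")
    if np.allclose(x, x[0]):
        raise ValueError("constant sample; normality undefined")
    res = stats.anderson(x, dist="norm")
    levels = np.asarray(res.significance_level, dtype=float)  # percent
    crit = np.asarray(res.critical_values, dtype=float)
    idx = int(np.argmin(np.abs(levels - alpha * 100)))
    significant = res.statistic > crit[idx]
    return "nonparametric" if significant else "parametric"


def gated_paired_comparison(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Paired comparison routed by the normality gate on the differences."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    route = anderson_darling_gate(d)
    result = paired_t(x, y) if route == "parametric" else wilcoxon_paired(x, y)
    result.flags = result.flags + (f"route={route}",)
    return result


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation coefficient with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("equal-length samples of n >= 3 required")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return TestResult(statistic=float(r), df=x.size - 2, p=float(p),
                      method="pearson")
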