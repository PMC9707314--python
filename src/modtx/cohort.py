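"""Baseline group-comparison statistics computable from printed summaries.

Standard demographic-table tests: two-sample t tests from summary statistics
(Welch by default), Pearson chi-squared on 2×2 proportion tables (no
continuity correction by default — with Yates the usual published values do
not reproduce), and Wilcoxon rank tests (rank-sum unpaired, signed-rank
paired; exact enumeration for small tie-free samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "t_test_from_summary",
    "chi2_test_2x2",
    "rank_tests",
]


@dataclass(frozen=True)
class GroupSummary:
    """Summary of one group: n with mean/sd, or n with a count of positives."""

    n: int
    mean: float | None = None
    sd: float | None = None
    count: int | None = None

    def __post_init__(self) -> None:
        if self.count is not None and not 0 <= self.count <= self.n:
            raise ValueError("count must be in [0, n]")


def t_test_from_summary(
    a: GroupSummary, b: GroupSummary, welch: bool = True
) -> tuple[float, float, float]:
    """Two-sample t test from (n, mean, sd) summaries; returns (t, df, p).

    Welch (unpooled) by default with Welch–Satterthwaite degrees of freedom;
    ``welch=False`` gives the pooled-variance variant.
    """
    for g in (a, b):
        if g.n < 2:
            raise ValueError("t test needs n >= 2 per group")
        if g.mean is None or g.sd is None or g.sd <= 0:
            raise ValueError("t test needs mean and sd > 0 per group")
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=not welch
    )
    if welch:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    else:
        df = a.n + b.n - 2
    return float(res.statistic), float(df), float(res.pvalue)


def chi2_test_2x2(
    count_a: int, n_a: int, count_b: int, n_b: int, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-squared (df=1) on a 2×2 proportions table; (chi2, p)."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("group totals must be > 0")
    table = np.array([[count_a, n_a - count_a], [count_b, n_b - count_b]])
    if np.any(table < 0):
        raise ValueError("counts cannot exceed totals")
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    if np.any(expected == 0):
        raise ValueError("a table margin is zero; chi-squared undefined")
    if np.all(table[0] * n_b == table[1] * n_a):
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)


def rank_tests(
    x, y, paired: bool = False
) -> tuple[float, float]:
    """Wilcoxon rank tests: rank-sum (unpaired) or signed-rank (paired).

    Uses exact enumeration when n <= 10 without ties, otherwise the normal
    approximation with tie correction.  Paired data whose differences are
    all zero give p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        d = x - y
        if np.all(d == 0):
            warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
            return 0.0, 1.0
        nz = d[d != 0]
        exact = len(nz) <= 10 and len(np.unique(np.abs(nz))) == len(nz)
        res = stats.wilcoxon(x, y, mode="exact" if exact else "approx",
                             correction=not exact)
        return float(res.statistic), float(res.pvalue)
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    exact = max(len(x), len(y)) <= 10 and not ties
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)
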