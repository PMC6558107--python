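"""Shared statistical test helpers (rank-sum policy used pipeline-wide)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Largest per-arm sample size for which the exact rank-sum null
#: distribution is used (ties force the normal approximation).
EXACT_LIMIT = 25


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann-Whitney U of the first sample
    p_value: float
    method: str  # "exact" | "asymptotic" | "degenerate"


def rank_sum_test(x, y) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when both arms are small and there
    are no ties, otherwise the normal approximation with tie and
    continuity corrections.  Identical constant samples short-circuit to
    p = 1 (the test is undefined there but exchangeability is exact).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test requires non-empty samples")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return RankSumResult(statistic=x.size * y.size / 2.0, p_value=1.0, method="degenerate")
    has_ties = np.unique(combined).size < combined.size
    if x.size <= EXACT_LIMIT and y.size <= EXACT_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return RankSumResult(statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)), method=method)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    return stats.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")
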