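"""Rank-based group comparisons and the p-value star coding used in figures."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "rank_test", "compare_groups", "p_stars"]


def p_stars(p: float) -> str:
    """Star-code a p-value: <0.0001 ****; 0.0001-0.001 ***; 0.001-0.01 **;
    0.01-0.05 *; otherwise ns."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    stars: str
    test: str


def rank_test(a, b, paired: bool = False) -> GroupComparison:
    """Rank-based two-group comparison.

    paired=True runs Wilcoxon's signed-rank test (equal sizes required);
    paired=False runs the rank-sum (Mann-Whitney U) variant for unpaired
    groups.  Identical paired samples (all zero differences) return p = 1
    by convention rather than raising.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal group sizes")
        d = a - b
        if np.all(d == 0):
            return GroupComparison(0.0, 1.0, "ns", "wilcoxon-signed-rank")
        res = sps.wilcoxon(a, b)
        return GroupComparison(
            float(res.statistic), float(res.pvalue), p_stars(res.pvalue),
            "wilcoxon-signed-rank",
        )
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        float(res.statistic), float(res.pvalue), p_stars(res.pvalue), "rank-sum"
    )


def compare_groups(
    group_a: dict[str, np.ndarray],
    group_b: dict[str, np.ndarray],
    paired: bool = False,
    names: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Per-parameter rank test between two groups of per-subject values.

    ``group_a`` / ``group_b`` map parameter name -> 1-D array of subject-level
    summaries (e.g. ROI means).  Returns a table with statistic, p-value and
    the star band per parameter.
    """
    params = [k for k in group_a if k in group_b]
    if not params:
        raise ValueError("no common parameters between the groups")
    rows = []
    for p in params:
        cmp = rank_test(group_a[p], group_b[p], paired=paired)
        rows.append(
            {
                "parameter": p,
                "group_a": names[0],
                "group_b": names[1],
                "mean_a": float(np.mean(group_a[p])),
                "mean_b": float(np.mean(group_b[p])),
                "test": cmp.test,
                "statistic": cmp.statistic,
                "p_value": cmp.p_value,
                "stars": cmp.stars,
            }
        )
    return pd.DataFrame(rows)
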