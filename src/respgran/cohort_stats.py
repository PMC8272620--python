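"""Cohort statistics: rank tests across pattern groups and boxplot summaries.

Anthropometric variables are compared across the normal / intermediate /
periodic-like groups with the Kruskal–Wallis test (rank-based, tie-corrected,
chi-square approximation for the p-value).  The published comparison table
reports pairwise group contrasts under the Kruskal–Wallis heading, so the
pairwise export here runs two-sample Kruskal–Wallis tests (equivalent to the
Wilcoxon rank-sum test up to the chi-square approximation).  The sex-by-group
association uses the Pearson chi-square test on the 2×3 contingency table.
P-values are uncorrected per-variable by default; Holm correction can be
switched on.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "BoxplotSummary",
    "kruskal_wallis",
    "chi_square_association",
    "boxplot_summary",
    "pairwise_comparisons",
    "DEFAULT_VARIABLES",
]

DEFAULT_VARIABLES = ("age", "weight_kg", "height_cm", "waist_cm", "hip_cm",
                     "bmi", "whr")


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    groups: tuple
    statistic: float
    p_value: float

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")
        if self.statistic < 0:
            raise ValueError("statistic must be non-negative")


@dataclass(frozen=True)
class BoxplotSummary:
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: tuple


def kruskal_wallis(samples: Mapping[str, Sequence[float]],
                   variable: str = "") -> GroupComparison:
    """Tie-corrected Kruskal–Wallis H test across labelled samples."""
    if len(samples) < 2:
        raise ValueError("at least two samples are required")
    arrays = []
    for name, s in samples.items():
        a = np.asarray(s, dtype=float)
        if a.size == 0:
            raise ValueError(f"sample {name!r} is empty")
        arrays.append(a)
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        # no rank variation at all: H = 0 by convention, p = 1
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    return GroupComparison(variable=variable, groups=tuple(samples),
                           statistic=float(h), p_value=float(min(p, 1.0)))


def chi_square_association(contingency) -> tuple[float, float]:
    """Pearson chi-square test of independence with (r−1)(c−1) df."""
    table = np.asarray(contingency, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(table, np.round(table)):
        raise ValueError("counts must be integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an all-zero margin")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def boxplot_summary(sample: Sequence[float]) -> BoxplotSummary:
    """Median, interpolated quartiles, 1.5·IQR whiskers and outliers."""
    a = np.asarray(sample, dtype=float)
    if a.size < 1:
        raise ValueError("sample must be non-empty")
    q1, med, q3 = np.percentile(a, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = a[(a >= lo_fence) & (a <= hi_fence)]
    outliers = tuple(sorted(a[(a < lo_fence) | (a > hi_fence)].tolist()))
    return BoxplotSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        whisker_lo=float(inside.min()), whisker_hi=float(inside.max()),
        outliers=outliers,
    )


def pairwise_comparisons(
    cohort: pd.DataFrame,
    variables: Sequence[str] = DEFAULT_VARIABLES,
    group_col: str = "expert_label",
    holm: bool = False,
) -> pd.DataFrame:
    """Pairwise two-sample Kruskal–Wallis p-values per variable.

    Mirrors the published comparison-table layout: one row per group pair,
    one column per variable.  ``holm`` applies a Holm step-down correction
    across each row's variables.
    """
    group_names = {1: "normal", 2: "intermediate", 3: "periodic-like"}
    levels = sorted(cohort[group_col].unique())
    rows = []
    for g1, g2 in combinations(levels, 2):
        row = {"group_1": group_names.get(g1, g1),
               "group_2": group_names.get(g2, g2)}
        pvals = {}
        for var in variables:
            cmp = kruskal_wallis({
                str(g1): cohort.loc[cohort[group_col] == g1, var],
                str(g2): cohort.loc[cohort[group_col] == g2, var],
            }, variable=var)
            pvals[var] = cmp.p_value
        if holm:
            order = sorted(pvals, key=pvals.get)
            m = len(order)
            adj, running = {}, 0.0
            for i, var in enumerate(order):
                running = max(running, (m - i) * pvals[var])
                adj[var] = min(1.0, running)
            pvals = adj
        row.update(pvals)
        rows.append(row)
    return pd.DataFrame(rows)
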