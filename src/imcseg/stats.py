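"""Two-group per-cell statistics and cross-layer fold-change concordance.

Group comparisons pool all segmented cells of one type per condition (no
per-sample aggregation or random effects, mirroring per-cell violin-plot
figures) and use Welch's unequal-variance t-test by default. Box summaries
follow Tukey's convention: median, quartiles, and adjacent values (the
extreme observations within 1.5×IQR of the quartiles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GroupComparison, GroupSummary

__all__ = [
    "TTestResult",
    "ViolinSummary",
    "welch_ttest",
    "violin_summary",
    "compare_groups",
    "cross_layer_concordance",
    "ConcordanceResult",
]


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float


@dataclass(frozen=True)
class ViolinSummary:
    median: float
    q1: float
    q3: float
    adjacent_low: float
    adjacent_high: float


@dataclass(frozen=True)
class ConcordanceResult:
    rho: float
    n_selected: int
    selected_ids: tuple


def welch_ttest(
    a: Sequence[float], b: Sequence[float], equal_var: bool = False
) -> TTestResult:
    """Independent two-sided t-test (Welch's unequal-variance variant by default).

    The t statistic is signed as mean(a) - mean(b); the degrees of freedom
    follow Welch-Satterthwaite (or n_a + n_b - 2 with ``equal_var=True``).
    When both groups have zero variance and equal means the test is degenerate
    and (t=0, p=1) is returned, with df reported as n_a + n_b - 2.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        pooled_df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return TTestResult(0.0, pooled_df, 1.0)
        t = np.inf if a.mean() > b.mean() else -np.inf
        return TTestResult(float(t), pooled_df, 0.0)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


def violin_summary(values: Sequence[float]) -> ViolinSummary:
    """Median, quartiles (linear interpolation) and Tukey adjacent values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("violin_summary needs at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    adjacent_low = float(v[v >= lo_fence].min())
    adjacent_high = float(v[v <= hi_fence].max())
    return ViolinSummary(float(med), float(q1), float(q3), adjacent_low, adjacent_high)


def compare_groups(
    table: pd.DataFrame,
    channel: str,
    cell_type: str,
    groups: tuple[str, str] | None = None,
    equal_var: bool = False,
) -> GroupComparison:
    """Compare one marker's per-cell arcsinh intensity between two groups.

    Cells of the requested type are pooled across ROIs and samples within
    each group. ``groups`` fixes the comparison order (t signed as first
    minus second); by default the two labels present are used in
    lexicographic order.
    """
    col = f"{channel}_arcsinh"
    if col not in table.columns:
        raise KeyError(f"channel {channel!r} not quantified in this table")
    sub = table[table["cell_type"] == cell_type]
    present = sorted(sub["group"].unique())
    if groups is None:
        if len(present) != 2:
            raise ValueError(f"expected exactly two groups, found {present}")
        groups = (present[0], present[1])
    ga, gb = groups
    a = sub.loc[sub["group"] == ga, col].to_numpy()
    b = sub.loc[sub["group"] == gb, col].to_numpy()
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"need >= 2 cells of type {cell_type!r} per group, got {a.size} vs {b.size}"
        )
    test = welch_ttest(a, b, equal_var=equal_var)

    def summarise(group: str, vals: np.ndarray) -> GroupSummary:
        s = violin_summary(vals)
        return GroupSummary(
            group=group,
            n=int(vals.size),
            median=s.median,
            q1=s.q1,
            q3=s.q3,
            adjacent_low=s.adjacent_low,
            adjacent_high=s.adjacent_high,
        )

    return GroupComparison(
        channel=channel,
        cell_type=cell_type,
        group_a=summarise(ga, a),
        group_b=summarise(gb, b),
        t_statistic=test.t_statistic,
        degrees_of_freedom=test.degrees_of_freedom,
        p_value=test.p_value,
    )


def cross_layer_concordance(
    fc_a: Mapping[str, float] | pd.Series,
    fc_b: Mapping[str, float] | pd.Series,
    threshold: float = 0.8,
    mode: str = "any",
) -> ConcordanceResult:
    """Spearman concordance of log2 fold changes shared between two layers.

    Identifiers present in both tables are selected when |log2FC| exceeds
    ``threshold`` in at least one layer (``mode="any"``, the default) or in
    both layers (``mode="both"``). Returns the Spearman rank correlation
    (average ranks for ties) over the selection, its size, and the selected
    identifiers.
    """
    if mode not in ("any", "both"):
        raise ValueError("mode must be 'any' or 'both'")
    sa = pd.Series(fc_a, dtype=float)
    sb = pd.Series(fc_b, dtype=float)
    shared = sa.index.intersection(sb.index)
    aa = sa.loc[shared].to_numpy()
    bb = sb.loc[shared].to_numpy()
    if mode == "any":
        sel = (np.abs(aa) > threshold) | (np.abs(bb) > threshold)
    else:
        sel = (np.abs(aa) > threshold) & (np.abs(bb) > threshold)
    ids = tuple(shared[sel])
    if len(ids) < 3:
        raise ValueError(
            f"only {len(ids)} identifiers pass the |log2FC| > {threshold} filter; "
            "need at least 3 for a rank correlation"
        )
    rho, _ = sps.spearmanr(aa[sel], bb[sel])
    return ConcordanceResult(rho=float(rho), n_selected=len(ids), selected_ids=ids)
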