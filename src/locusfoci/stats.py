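"""Group statistics: Student's t, one-way ANOVA with Tukey HSD, Tukey box
summaries, and fold change of group means.

Two-group comparisons use the pooled-variance two-sided Student's t test.
Comparisons among more than two groups use a one-way ANOVA followed by
Tukey's multiple-comparisons test at alpha = 0.05, in the Tukey-Kramer form
for unbalanced groups, with adjusted p values from the studentized range
distribution.  Box summaries follow the Tukey convention: box at the
quartiles (linear interpolation), whiskers at the most extreme data within
1.5 x IQR, points beyond flagged as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "AnovaTukeyResult",
    "TukeyBoxSummary",
    "student_t",
    "one_way_anova",
    "tukey_hsd",
    "tukey_box",
    "fold_change",
]


@dataclass
class GroupSample:
    """A labeled sample of measurements (SNR, efficiency ratios, nm distances)."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass
class PairwiseComparison:
    label_a: str
    label_b: str
    mean_diff: float
    q: float
    p_adjusted: float

    @property
    def significant_label(self) -> str:
        p = self.p_adjusted
        if p >= 0.05:
            return "ns"
        if p >= 0.01:
            return "*"
        if p >= 0.001:
            return "**"
        if p >= 0.0001:
            return "***"
        return "****"


@dataclass
class AnovaTukeyResult:
    F: float
    df_between: int
    df_within: int
    p_overall: float
    pairwise: list = field(default_factory=list)
    alpha: float = 0.05


@dataclass
class TukeyBoxSummary:
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def _check_groups(groups: Sequence[GroupSample], min_k: int = 2) -> None:
    if len(groups) < min_k:
        raise ValueError(f"need at least {min_k} groups, got {len(groups)}")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.label!r} has n={g.n}; inferential use needs n >= 2")


def student_t(a: GroupSample, b: GroupSample) -> tuple[float, int, float]:
    """Pooled-variance two-sided Student's t test. Returns ``(t, df, p)``."""
    _check_groups([a, b])
    df = a.n + b.n - 2
    ssa = float(((a.values - a.mean) ** 2).sum())
    ssb = float(((b.values - b.mean) ** 2).sum())
    pooled_var = (ssa + ssb) / df
    if pooled_var == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    t = (a.mean - b.mean) / np.sqrt(pooled_var * (1.0 / a.n + 1.0 / b.n))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return float(t), df, p


def one_way_anova(groups: Sequence[GroupSample]) -> tuple[float, int, int, float]:
    """Standard between/within decomposition. Returns ``(F, df_b, df_w, p)``."""
    _check_groups(groups)
    all_vals = np.concatenate([g.values for g in groups])
    grand = all_vals.mean()
    ssb = sum(g.n * (g.mean - grand) ** 2 for g in groups)
    ssw = sum(float(((g.values - g.mean) ** 2).sum()) for g in groups)
    df_b = len(groups) - 1
    df_w = all_vals.size - len(groups)
    if ssw == 0:
        raise ValueError("zero within-group variance everywhere: F undefined")
    F = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return float(F), df_b, df_w, p


def tukey_hsd(groups: Sequence[GroupSample], alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way ANOVA followed by Tukey's multiple-comparisons test.

    The Tukey-Kramer statistic for groups i, j is
    ``q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))`` and the
    adjusted p value is the studentized-range tail probability with k groups
    and the within-group degrees of freedom.
    """
    F, df_b, df_w, p_overall = one_way_anova(groups)
    k = len(groups)
    ssw = sum(float(((g.values - g.mean) ** 2).sum()) for g in groups)
    msw = ssw / df_w
    pairwise = []
    for ga, gb in combinations(groups, 2):
        diff = ga.mean - gb.mean
        se = np.sqrt(msw / 2.0 * (1.0 / ga.n + 1.0 / gb.n))
        q = abs(diff) / se
        p_adj = float(np.clip(sps.studentized_range.sf(q, k, df_w), 0.0, 1.0))
        pairwise.append(PairwiseComparison(ga.label, gb.label, float(diff), float(q), p_adj))
    return AnovaTukeyResult(
        F=F, df_between=df_b, df_within=df_w, p_overall=p_overall,
        pairwise=pairwise, alpha=alpha,
    )


def tukey_box(values: Sequence[float]) -> TukeyBoxSummary:
    """Tukey box-plot summary of one sample.

    Quartiles by linear interpolation (type-7); whiskers at the most extreme
    data points within ``[q1 - 1.5*IQR, q3 + 1.5*IQR]``; whiskers are always
    actual data values.
    """
    vals = np.asarray(values, dtype=np.float64).ravel()
    if vals.size < 1:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
    outliers = vals[(vals < lo_fence) | (vals > hi_fence)]
    return TukeyBoxSummary(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=np.sort(outliers),
    )


def fold_change(means: Sequence[float]) -> float:
    """``max(means) / min(means)``; all means must be strictly positive."""
    arr = np.asarray(means, dtype=np.float64).ravel()
    if arr.size == 0:
        raise ValueError("need at least one mean")
    if np.any(arr <= 0):
        raise ValueError("fold change needs strictly positive means")
    return float(arr.max() / arr.min())
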