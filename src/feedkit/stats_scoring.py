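"""Paired comparisons, index performance scoring, and method agreement.

A hunger effect is the within-subject difference between hunger and
satiety internal states at a fixed food; a palatability effect is the
difference between palatable and unpalatable food at a fixed state.
With three subjects, inferential power is limited, so two complementary
summaries are used: the paired two-sample t-test p-value, and the
"altogether" flag — true when every subject's difference has the same
(nonzero) sign.

Each index accrues a performance score per condition: 1 point when the
change is altogether-consistent, plus 1 point for p < 0.05 or 2 points
for p < 0.01; points sum across the replicate conditions to rank the
indices.

Manual-vs-pose-route agreement is summarised by Pearson correlation
(r, R², two-tailed p) and a Bland–Altman analysis: bias (mean
difference), SD of bias, and bias ± 1.96·SD limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .indices import IndexTable

__all__ = [
    "PairedComparison",
    "PerformanceScore",
    "AgreementStats",
    "Plot2D",
    "paired_compare",
    "performance_score",
    "agreement",
    "plot2d",
    "bonferroni",
]

LOA_MULTIPLIER = 1.96


@dataclass
class PairedComparison:
    """Result of one within-subject two-condition comparison."""

    values_a: np.ndarray
    values_b: np.ndarray
    mean_difference: float
    p_value: Optional[float]
    altogether: bool
    test: str = "t"

    @property
    def differences(self) -> np.ndarray:
        return self.values_a - self.values_b


@dataclass
class PerformanceScore:
    """Points an index earns from one comparison."""

    direction_points: int
    significance_points: int
    note: str = ""

    @property
    def total(self) -> int:
        return self.direction_points + self.significance_points


@dataclass
class AgreementStats:
    """Bland–Altman and correlation summary of two measurement routes."""

    bias: float
    sd_of_bias: float
    loa_low: float
    loa_high: float
    pearson_r: Optional[float]
    r_squared: Optional[float]
    p_two_tailed: Optional[float]
    n: int


@dataclass
class Plot2D:
    """Palatability-specific (x) vs hunger-specific (y) index coordinates.

    ``coords[(subject, state, food)] = (x, y)``.  The normalized variant
    divides each subject's values by that subject's hunger–palatable
    cell, which therefore maps to exactly (1, 1).
    """

    coords: dict[tuple[str, str, str], tuple[float, float]]
    x_index: str
    y_index: str
    normalized: bool


def paired_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    test: str = "t",
) -> PairedComparison:
    """Two-sided paired comparison of matched per-subject values.

    ``test`` is ``"t"`` (paired two-sample t-test, the default) or
    ``"wilcoxon"`` (signed-rank).  ``altogether`` is true iff every
    per-subject difference is nonzero and all share one sign; a zero
    difference conservatively breaks it.  Zero variance of the
    differences leaves the p-value missing.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal length")
    if len(a) < 2:
        raise ValueError("paired comparison needs at least 2 pairs")
    d = a - b
    altogether = bool(np.all(d > 0) or np.all(d < 0))
    if np.ptp(d) == 0 and test == "t":
        p = None  # zero variance: the t statistic is undefined
    elif test == "t":
        p = float(stats.ttest_rel(a, b).pvalue)
    elif test == "wilcoxon":
        if np.all(d == 0):
            p = None
        else:
            p = float(stats.wilcoxon(a, b).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return PairedComparison(
        values_a=a,
        values_b=b,
        mean_difference=float(d.mean()),
        p_value=p,
        altogether=altogether,
        test=test,
    )


def performance_score(cmp: PairedComparison) -> PerformanceScore:
    """Score one comparison: direction point plus significance points.

    1 point when all subjects move in the same direction; 1 point for
    p < 0.05, or 2 for p < 0.01.  Direction and significance points can
    both accrue from the same comparison.  A missing p-value earns no
    significance points.
    """
    direction = 1 if cmp.altogether else 0
    if cmp.p_value is None or np.isnan(cmp.p_value):
        return PerformanceScore(direction, 0, note="p-value missing")
    if cmp.p_value < 0.01:
        sig = 2
    elif cmp.p_value < 0.05:
        sig = 1
    else:
        sig = 0
    return PerformanceScore(direction, sig)


def bonferroni(p_values: Sequence[Optional[float]]) -> list[Optional[float]]:
    """Bonferroni-adjusted p-values (family size = number of non-missing)."""
    ps = [p for p in p_values if p is not None and not np.isnan(p)]
    m = len(ps)
    return [
        None if (p is None or np.isnan(p)) else min(1.0, p * m) for p in p_values
    ]


def agreement(
    values_manual: Sequence[float], values_deep: Sequence[float]
) -> AgreementStats:
    """Bland–Altman and Pearson agreement between two measurement routes.

    Bias is mean(manual − deep); limits of agreement are
    bias ± 1.96·SD of the differences (sample SD).  Correlation fields
    are missing for n < 3 or when either vector is constant.
    """
    m = np.asarray(values_manual, float)
    d = np.asarray(values_deep, float)
    if m.shape != d.shape or m.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal length")
    n = len(m)
    if n < 2:
        raise ValueError("agreement needs at least 2 pairs")
    diff = m - d
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    r = r2 = p = None
    if n >= 3 and np.ptp(m) > 0 and np.ptp(d) > 0:
        res = stats.pearsonr(m, d)
        r = float(res.statistic)
        r2 = r * r
        p = float(res.pvalue)
    return AgreementStats(
        bias=bias,
        sd_of_bias=sd,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        pearson_r=r,
        r_squared=r2,
        p_two_tailed=p,
        n=n,
    )


_STATES = ("hunger", "satiety")
_FOODS = ("palatable", "unpalatable")


def plot2d(
    table: IndexTable,
    x_index: str,
    y_index: str,
    normalize: bool = False,
    x_condition: Optional[str] = None,
    y_condition: Optional[str] = None,
) -> Plot2D:
    """2D coordinates placing each (subject, state, food) cell by a
    palatability-specific index (x) and a hunger-specific index (y).

    ``x_condition`` / ``y_condition`` select which replicate condition
    each axis is read from (default: the single condition present).
    With ``normalize``, every subject's coordinates are divided by that
    subject's hunger–palatable values, pinning that cell at (1, 1).
    """
    df = table.to_frame()

    def _axis_values(code: str, condition: Optional[str]) -> dict:
        sel = df[df["index"] == code]
        if condition is not None:
            sel = sel[sel["condition"] == condition]
        out = {}
        for _, rec in sel.iterrows():
            key = (rec["subject"], rec["internal_state"], rec["food"])
            out[key] = float(rec["value"])
        return out

    xv = _axis_values(x_index, x_condition)
    yv = _axis_values(y_index, y_condition)
    subjects = sorted({s for s, _, _ in xv} | {s for s, _, _ in yv})
    coords = {}
    for subj in subjects:
        for state in _STATES:
            for food in _FOODS:
                key = (subj, state, food)
                if key not in xv or key not in yv:
                    raise ValueError(
                        f"missing ({state}, {food}) cell for subject {subj}"
                    )
        if normalize:
            ref_x = xv[(subj, "hunger", "palatable")]
            ref_y = yv[(subj, "hunger", "palatable")]
            if ref_x == 0 or ref_y == 0:
                raise ValueError(
                    f"subject {subj}: hunger-palatable reference value is 0; "
                    "cannot normalize"
                )
        for state in _STATES:
            for food in _FOODS:
                key = (subj, state, food)
                x, y = xv[key], yv[key]
                if normalize:
                    x, y = x / ref_x, y / ref_y
                coords[key] = (x, y)
    return Plot2D(
        coords=coords, x_index=x_index, y_index=y_index, normalized=normalize
    )
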