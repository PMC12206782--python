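"""Group-level aggregation and nonparametric comparison.

Per-subject series statistics (mean, sample SD, CV) are aggregated into
per-group summary tables with equal subject weighting (a pooled-stride
variant is available behind a flag), compared across groups with the
tie-corrected Kruskal–Wallis rank test, and ranked by group mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gait_io import Group

__all__ = [
    "GroupSummary",
    "KWResult",
    "subject_summary",
    "group_table",
    "kruskal_wallis",
    "rank_groups",
    "GROUP_ORDER",
]

#: Canonical column order for summary tables.
GROUP_ORDER: tuple[Group, ...] = (Group.ALS, Group.PD, Group.HD, Group.CTRL)


@dataclass
class GroupSummary:
    """One group x one series/feature: mean, SD and CV over subjects."""

    group: Group
    series_or_feature: str
    mean: float
    sd: float
    cv: float  # percent; NaN when the mean is 0
    n_subjects: int
    single_subject: bool = False  # SD is 0 by convention, flagged

    def cell(self) -> str:
        """Render as the conventional ``mean ± sd`` table cell."""
        return f"{self.mean:.4f} ± {self.sd:.4f}"


@dataclass
class KWResult:
    """Kruskal–Wallis H (tie-corrected) with chi-square p-value."""

    H: float
    p_value: float
    group_ns: dict[Group, int]


def subject_summary(series: Sequence[float]) -> tuple[float, float, float]:
    """Arithmetic mean, sample SD (n-1 denominator) and CV = 100*sd/mean."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values for a sample SD")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else math.nan
    return mean, sd, cv


def group_table(
    per_subject: pd.DataFrame,
    value_col: str,
    feature_name: str | None = None,
    weights_col: str | None = None,
) -> list[GroupSummary]:
    """Aggregate a per-subject statistic into per-group summaries.

    ``per_subject`` needs columns ``group`` (Group or its value) and
    ``value_col``. Default is equal subject weighting: group mean and
    sample SD over the subjects' values. With ``weights_col`` (e.g. a
    stride count) the mean is the pooled, weight-proportional variant;
    both modes label their rows via ``GroupSummary.series_or_feature``.
    Unknown group labels raise.
    """
    feature_name = feature_name or value_col
    out: list[GroupSummary] = []
    for grp, sub in per_subject.groupby("group", sort=False):
        group = Group(grp)  # raises on unknown labels
        vals = sub[value_col].to_numpy(dtype=float)
        if weights_col is None:
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            label = feature_name
        else:
            w = sub[weights_col].to_numpy(dtype=float)
            mean = float(np.average(vals, weights=w))
            sd = float(np.sqrt(np.average((vals - mean) ** 2, weights=w))) if vals.size > 1 else 0.0
            label = f"{feature_name}[pooled]"
        out.append(
            GroupSummary(
                group=group,
                series_or_feature=label,
                mean=mean,
                sd=sd,
                cv=100.0 * sd / mean if mean != 0 else math.nan,
                n_subjects=int(vals.size),
                single_subject=vals.size == 1,
            )
        )
    return out


def kruskal_wallis(samples: Sequence[Sequence[float]], groups: Sequence[Group] | None = None) -> KWResult:
    """Tie-corrected Kruskal–Wallis H with chi-square(k-1) p-value.

    When every pooled observation is identical the statistic is 0 and
    p = 1 (scipy raises on this degenerate case; it is well-defined).
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(s.size == 0 for s in samples):
        raise ValueError("every group must be nonempty")
    if groups is None:
        groups = list(GROUP_ORDER[: len(samples)])
    ns = {g: int(s.size) for g, s in zip(groups, samples)}
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return KWResult(H=0.0, p_value=1.0, group_ns=ns)
    H, p = stats.kruskal(*samples)
    return KWResult(H=float(H), p_value=float(p), group_ns=ns)


def rank_groups(
    summaries: Sequence[GroupSummary], feature: str | None = None
) -> tuple[list[Group], bool]:
    """Groups sorted by descending mean; returns ``(order, tie_flag)``.

    Expects exactly one summary per group of :data:`GROUP_ORDER` (for the
    given feature, if named); ties are broken lexicographically on the
    group name and flagged.
    """
    rows = [s for s in summaries if feature is None or s.series_or_feature == feature]
    seen = {s.group for s in rows}
    missing = [g for g in GROUP_ORDER if g not in seen]
    if missing or len(rows) != len(GROUP_ORDER):
        raise ValueError(f"need one summary per group; missing {missing or 'duplicates'}")
    means = {s.group: s.mean for s in rows}
    order = sorted(means, key=lambda g: (-means[g], g.value))
    vals = sorted(means.values(), reverse=True)
    tie = any(a == b for a, b in zip(vals, vals[1:]))
    return order, tie
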