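"""Preprocessing of stride-indexed gait series.

Four steps precede feature extraction: trimming the unstable start-up
strides, optional outlier deletion, the left/right ratio transform (the
element-wise quotient of paired interval series, 1 = perfect symmetry),
and a width-n running median with edge replication, which suppresses the
isolated spikes that corridor turns leave in interval series while
preserving the underlying trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .gait_io import GaitRecord, Phase, RATIO_PAIRS, Side, SeriesKind, Unit

__all__ = [
    "MedianFilterParams",
    "RatioSeries",
    "PreprocessConfig",
    "median_filter",
    "lr_ratio",
    "ratio_series_for",
    "all_ratio_series",
    "trim_startup",
    "remove_outliers",
]


@dataclass(frozen=True)
class MedianFilterParams:
    """Running-median window: odd width ``n = 2k + 1`` strides (default 3)."""

    n: int = 3

    def __post_init__(self) -> None:
        if self.n < 1 or self.n % 2 == 0:
            raise ValueError(f"median filter width must be odd and >= 1, got {self.n}")

    @property
    def k(self) -> int:
        return (self.n - 1) // 2


@dataclass
class RatioSeries:
    """Element-wise left/right quotient for one interval kind.

    ``n_pairs_used + n_pairs_dropped`` equals the number of aligned pairs
    (the shorter of the two input lengths); pairs where either side is
    non-positive are dropped, so all retained values are > 0.
    """

    values: np.ndarray
    n_pairs_used: int
    n_pairs_dropped: int
    phase: Phase | None = None
    unit: Unit | None = None

    @property
    def name(self) -> str:
        if self.phase is None or self.unit is None:
            return "ratio"
        unit = "s" if self.unit is Unit.SECONDS else "pct"
        return f"ratio_{self.phase.value}_{unit}"


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing switches, echoed into output provenance.

    startup_trim
        Strides with elapsed time below this many seconds are dropped;
        20 s by default, the conventional settle-in allowance for this
        database (the acquisition protocol starts the recorder with the
        subject stationary).
    outlier_rule
        ``"none"`` or ``"median_3sd"``; applied (when enabled) before
        group statistics only — denoising ahead of feature extraction is
        the median filter's job.
    filter
        Median-filter window.
    filter_before_ratio
        If True, left and right series are median-filtered before the
        ratio is taken; default False (ratio first, then filter).
    """

    startup_trim: float = 20.0
    outlier_rule: str = "none"
    filter: MedianFilterParams = field(default_factory=MedianFilterParams)
    filter_before_ratio: bool = False

    def __post_init__(self) -> None:
        if self.startup_trim < 0:
            raise ValueError("startup_trim must be >= 0")
        if self.outlier_rule not in ("none", "median_3sd"):
            raise ValueError(f"unknown outlier rule {self.outlier_rule!r}")


def median_filter(x: Sequence[float], params: MedianFilterParams | int = 3) -> np.ndarray:
    """Width-n running median with edge replication.

    Element i of the output is the median of the window of width
    ``n = 2k + 1`` centred on i, with the first value repeated k times
    before the series and the last value k times after it, so the output
    has the same length as the input. ``n`` must be odd (the median of an
    odd window is always a data value).
    """
    if isinstance(params, int):
        params = MedianFilterParams(params)
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("input must be a non-empty 1-D sequence")
    if params.n == 1:
        return x.copy()
    return ndimage.median_filter(x, size=params.n, mode="nearest")


def lr_ratio(
    left: Sequence[float],
    right: Sequence[float],
    phase: Phase | None = None,
    unit: Unit | None = None,
) -> RatioSeries:
    """Element-wise left(i)/right(i) over the aligned pairs.

    Pairs with a non-positive member are dropped and counted in
    ``n_pairs_dropped``. Raises if every pair is dropped.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.size == 0 or right.size == 0:
        raise ValueError("both sequences must be non-empty")
    m = min(left.size, right.size)
    l, r = left[:m], right[:m]
    keep = (l > 0) & (r > 0)
    if not keep.any():
        raise ValueError("all left/right pairs dropped; empty ratio series")
    values = l[keep] / r[keep]
    return RatioSeries(
        values=values,
        n_pairs_used=int(values.size),
        n_pairs_dropped=int(m - values.size),
        phase=phase,
        unit=unit,
    )


def ratio_series_for(
    rec: GaitRecord, phase: Phase, unit: Unit, cfg: PreprocessConfig | None = None
) -> RatioSeries:
    """Build the :class:`RatioSeries` of one phase/unit pair from a record."""
    cfg = cfg or PreprocessConfig()
    left = rec.series[SeriesKind(Side.LEFT, phase, unit)]
    right = rec.series[SeriesKind(Side.RIGHT, phase, unit)]
    if cfg.filter_before_ratio:
        left = median_filter(left, cfg.filter)
        right = median_filter(right, cfg.filter)
    return lr_ratio(left, right, phase=phase, unit=unit)


def all_ratio_series(rec: GaitRecord, cfg: PreprocessConfig | None = None) -> list[RatioSeries]:
    """The five left/right ratio series of a record (stride, swing s/%, stance s/%)."""
    return [ratio_series_for(rec, ph, un, cfg) for ph, un in RATIO_PAIRS]


def trim_startup(rec: GaitRecord, cfg: PreprocessConfig) -> GaitRecord:
    """Drop the strides recorded before ``startup_trim`` seconds, consistently
    from elapsed time and every interval series."""
    keep = rec.elapsed_time >= cfg.startup_trim
    if not keep.any():
        raise ValueError(
            f"startup_trim={cfg.startup_trim} s removes the whole record "
            f"(last stride at {rec.elapsed_time[-1]:.1f} s)"
        )
    if keep.all():
        return rec
    return GaitRecord(
        subject_id=rec.subject_id,
        group=rec.group,
        elapsed_time=rec.elapsed_time[keep],
        series={k: v[keep] for k, v in rec.series.items()},
    )


def remove_outliers(x: Sequence[float], rule: str = "median_3sd") -> tuple[np.ndarray, np.ndarray]:
    """Delete gross outliers: points farther than 3 sample SDs from the median.

    Returns ``(kept_values, removed_indices)``. With ``rule="none"`` this is
    the identity. A constant sequence (SD 0) loses nothing.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if rule == "none":
        return x.copy(), np.empty(0, dtype=int)
    if rule != "median_3sd":
        raise ValueError(f"unknown outlier rule {rule!r}")
    med = np.median(x)
    sd = np.std(x, ddof=1)
    out = np.abs(x - med) > 3.0 * sd
    return x[~out], np.flatnonzero(out)
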