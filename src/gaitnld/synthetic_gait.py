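"""Synthetic gaitndd-format cohorts with the statistical structure the
analysis assumes.

Each subject's left stride series is an AR(1) Gaussian fluctuation around
a subject-specific mean, truncated to physical values; the right stride is
the left divided by a subject-specific asymmetry ratio plus independent
left-right noise; swing is a noisy fraction of stride and stance its exact
complement, so stride = swing + stance holds identically and the percent
columns are exactly 100*phase/stride. Sparse large spikes emulate the
turns a subject makes walking a 77 m corridor for five minutes.

Default presets are calibrated per group (ALS, PD, HD, control) to the
published gaitndd summary statistics and shipped as
``data/group_presets.csv``; see ``docs/methods.md`` for the calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .gait_io import GaitRecord, Group, Phase, SERIES_COLUMNS, Side, SeriesKind, Unit

__all__ = [
    "GroupPreset",
    "SimConfig",
    "default_presets",
    "generate_subject",
    "generate_cohort",
    "inject_invalid",
    "write_cohort",
]

#: Lower truncation for interval values, seconds (prevents non-physical strides).
MIN_STRIDE_S = 0.3

#: gaitndd file-name stems per group.
GROUP_STEM = {Group.ALS: "als", Group.PD: "park", Group.HD: "hunt", Group.CTRL: "control"}


@dataclass(frozen=True)
class GroupPreset:
    """Statistical targets for one group's synthetic subjects.

    stride_mean_s, stride_sd_s
        Group mean stride time and the within-subject (stride-to-stride)
        SD, seconds.
    between_sd_s
        SD of subject means about the group mean, seconds.
    asymmetry, asymmetry_sd
        Mean left/right stride ratio and its between-subject SD.
    cross_noise_s
        SD of the independent noise on the right stride, seconds — sets
        the within-subject spread of the ratio series.
    swing_fraction, swing_noise_s
        Mean swing/stride fraction and the noise on swing, seconds.
    ar1
        Lag-1 autocorrelation of the stride fluctuations, in [0, 1).
    turn_rate, turn_scale
        Per-stride probability of a corridor-turn spike and the
        multiplier it applies to both sides' stride (> 1).
    """

    stride_mean_s: float
    stride_sd_s: float
    between_sd_s: float
    asymmetry: float
    asymmetry_sd: float
    cross_noise_s: float
    swing_fraction: float
    swing_noise_s: float
    ar1: float
    turn_rate: float
    turn_scale: float
    n_subjects: int

    def __post_init__(self) -> None:
        if self.stride_mean_s <= 0:
            raise ValueError("stride_mean_s must be > 0")
        if self.turn_scale <= 1:
            raise ValueError("turn_scale must be > 1")
        if not 0 <= self.ar1 < 1:
            raise ValueError("ar1 must be in [0, 1)")
        if not 0 < self.swing_fraction < 1:
            raise ValueError("swing_fraction must be in (0, 1)")
        if not 0 <= self.turn_rate < 1:
            raise ValueError("turn_rate must be in [0, 1)")
        if min(self.stride_sd_s, self.between_sd_s, self.asymmetry_sd,
               self.cross_noise_s, self.swing_noise_s) < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings (5-minute walks by default)."""

    presets: dict[Group, GroupPreset] = field(default_factory=lambda: default_presets())
    duration_s: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")


def default_presets() -> dict[Group, GroupPreset]:
    """Load the calibrated per-group presets shipped with the package."""
    with resources.files("gaitnld.data").joinpath("group_presets.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    out: dict[Group, GroupPreset] = {}
    for row in df.to_dict("records"):
        grp = Group(row.pop("group"))
        row["n_subjects"] = int(row["n_subjects"])
        out[grp] = GroupPreset(**row)
    return out


def _ar1_series(rng: np.random.Generator, n: int, sd: float, ar1: float) -> np.ndarray:
    """Stationary zero-mean AR(1) with marginal SD ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    z = np.empty(n)
    z[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - ar1**2)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        z[i] = ar1 * z[i - 1] + eps[i - 1]
    return z


def _swing_stance(
    rng: np.random.Generator, stride: np.ndarray, frac: float, noise_sd: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    swing = frac * stride + rng.normal(0.0, noise_sd, size=stride.size)
    # keep swing strictly inside (0, stride)
    swing = np.clip(swing, 0.1 * stride, 0.9 * stride)
    stance = stride - swing
    # re-derive stride as the literal float sum so the additivity identity
    # swing + stance == stride holds bit-exactly downstream
    stride = swing + stance
    return stride, swing, stance, 100.0 * swing / stride, 100.0 * stance / stride


def generate_subject(
    preset: GroupPreset,
    seed: int | np.random.SeedSequence,
    subject_id: str = "synth1",
    group: Group = Group.CTRL,
    duration_s: float = 300.0,
) -> GaitRecord:
    """One synthetic subject's 13-column gait record (reproducible per seed)."""
    rng = np.random.default_rng(seed)
    n = max(int(round(duration_s / preset.stride_mean_s)), 4)

    subj_mean = max(rng.normal(preset.stride_mean_s, preset.between_sd_s), 2 * MIN_STRIDE_S)
    subj_asym = max(rng.normal(preset.asymmetry, preset.asymmetry_sd), 0.5)

    left = subj_mean + _ar1_series(rng, n, preset.stride_sd_s, preset.ar1)
    left = np.maximum(left, MIN_STRIDE_S)
    right = left / subj_asym + rng.normal(0.0, preset.cross_noise_s, size=n)
    right = np.maximum(right, MIN_STRIDE_S)

    # corridor-turn artifacts hit both feet on the same stride
    turns = rng.random(n) < preset.turn_rate
    left = np.where(turns, left * preset.turn_scale, left)
    right = np.where(turns, right * preset.turn_scale, right)

    left, lsw, lst, lsw_pct, lst_pct = _swing_stance(rng, left, preset.swing_fraction, preset.swing_noise_s)
    right, rsw, rst, rsw_pct, rst_pct = _swing_stance(rng, right, preset.swing_fraction, preset.swing_noise_s)

    ds = np.maximum(lst + rst - left, 0.01)
    ds_pct = 100.0 * ds / left

    series = {
        SeriesKind(Side.LEFT, Phase.STRIDE, Unit.SECONDS): left,
        SeriesKind(Side.RIGHT, Phase.STRIDE, Unit.SECONDS): right,
        SeriesKind(Side.LEFT, Phase.SWING, Unit.SECONDS): lsw,
        SeriesKind(Side.RIGHT, Phase.SWING, Unit.SECONDS): rsw,
        SeriesKind(Side.LEFT, Phase.SWING, Unit.PERCENT): lsw_pct,
        SeriesKind(Side.RIGHT, Phase.SWING, Unit.PERCENT): rsw_pct,
        SeriesKind(Side.LEFT, Phase.STANCE, Unit.SECONDS): lst,
        SeriesKind(Side.RIGHT, Phase.STANCE, Unit.SECONDS): rst,
        SeriesKind(Side.LEFT, Phase.STANCE, Unit.PERCENT): lst_pct,
        SeriesKind(Side.RIGHT, Phase.STANCE, Unit.PERCENT): rst_pct,
        SeriesKind(Side.BOTH, Phase.DOUBLE_SUPPORT, Unit.SECONDS): ds,
        SeriesKind(Side.BOTH, Phase.DOUBLE_SUPPORT, Unit.PERCENT): ds_pct,
    }
    return GaitRecord(
        subject_id=subject_id, group=group, elapsed_time=np.cumsum(left), series=series
    )


def generate_cohort(cfg: SimConfig | None = None) -> list[GaitRecord]:
    """A full cohort, ``n_subjects`` records per group, deterministic per seed."""
    cfg = cfg or SimConfig()
    root = np.random.SeedSequence(cfg.seed)
    records: list[GaitRecord] = []
    seen: set[str] = set()
    for group in (Group.ALS, Group.PD, Group.HD, Group.CTRL):
        preset = cfg.presets.get(group)
        if preset is None or preset.n_subjects == 0:
            continue
        children = root.spawn(preset.n_subjects)
        for i, child in enumerate(children, start=1):
            sid = f"{GROUP_STEM[group]}{i}"
            if sid in seen:
                raise ValueError(f"duplicate subject id {sid}")
            seen.add(sid)
            records.append(
                generate_subject(preset, child, subject_id=sid, group=group,
                                 duration_s=cfg.duration_s)
            )
    return records


def inject_invalid(rec: GaitRecord, index: int) -> GaitRecord:
    """Negate one left-stride interval, producing the database's corrupt-
    record signature (a negative value) for exercising the exclusion path."""
    left_kind = SeriesKind(Side.LEFT, Phase.STRIDE, Unit.SECONDS)
    if not 0 <= index < rec.n_strides:
        raise IndexError(f"index {index} out of range for {rec.n_strides} strides")
    series = {k: v.copy() for k, v in rec.series.items()}
    series[left_kind][index] = -series[left_kind][index]
    return GaitRecord(
        subject_id=rec.subject_id,
        group=rec.group,
        elapsed_time=rec.elapsed_time.copy(),
        series=series,
    )


def write_cohort(records: Iterable[GaitRecord], out_dir) -> pd.DataFrame:
    """Write gaitndd text files plus a manifest CSV; returns the manifest."""
    from pathlib import Path

    from .gait_io import write_record

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        path = out / f"{rec.subject_id}.ts"
        with open(path, "w") as fh:
            write_record(rec, fh)
        rows.append(
            {"subject_id": rec.subject_id, "group": rec.group.value,
             "n_strides": rec.n_strides, "path": path.name}
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
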