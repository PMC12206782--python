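"""Reading, validating and writing gait interval records.

The on-disk layout is the gaitndd (gait in neurodegenerative disease)
database format: whitespace-delimited text, one row per stride, 13 numeric
columns — elapsed time in seconds followed by 12 left/right interval
series (stride, swing and stance in seconds and as % of stride, plus
double support in seconds and % of stride). There is no header line.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "Side",
    "Phase",
    "Unit",
    "SeriesKind",
    "GaitRecord",
    "ValidationFinding",
    "ParseError",
    "SERIES_COLUMNS",
    "RATIO_PAIRS",
    "parse_record",
    "read_record",
    "write_record",
    "validate_record",
    "write_features_csv",
    "read_features_csv",
]


class Group(str, Enum):
    """Study cohort: three neurodegenerative diseases plus healthy controls."""

    ALS = "ALS"
    PD = "PD"
    HD = "HD"
    CTRL = "CTRL"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    BOTH = "both"  # double support only


class Phase(str, Enum):
    STRIDE = "stride"
    SWING = "swing"
    STANCE = "stance"
    DOUBLE_SUPPORT = "double_support"


class Unit(str, Enum):
    SECONDS = "seconds"
    PERCENT = "percent_of_stride"


@dataclass(frozen=True)
class SeriesKind:
    """Identity of one interval series: which side, gait phase and unit.

    Percent series are on the 0-100 scale. ``side == BOTH`` is only valid
    for double support, which is not attributed to a single foot.
    """

    side: Side
    phase: Phase
    unit: Unit

    def __post_init__(self) -> None:
        if (self.side is Side.BOTH) != (self.phase is Phase.DOUBLE_SUPPORT):
            raise ValueError(
                "side 'both' is valid exactly for the double_support phase"
            )
        if self.phase is Phase.STRIDE and self.unit is Unit.PERCENT:
            raise ValueError("stride duration has no percent-of-stride form")

    @property
    def name(self) -> str:
        unit = "s" if self.unit is Unit.SECONDS else "pct"
        return f"{self.side.value}_{self.phase.value}_{unit}"

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.name


def _sk(side: Side, phase: Phase, unit: Unit) -> SeriesKind:
    return SeriesKind(side, phase, unit)


#: The 12 interval columns of a gaitndd record, in file order
#: (columns 2-13; column 1 is elapsed time).
SERIES_COLUMNS: tuple[SeriesKind, ...] = (
    _sk(Side.LEFT, Phase.STRIDE, Unit.SECONDS),
    _sk(Side.RIGHT, Phase.STRIDE, Unit.SECONDS),
    _sk(Side.LEFT, Phase.SWING, Unit.SECONDS),
    _sk(Side.RIGHT, Phase.SWING, Unit.SECONDS),
    _sk(Side.LEFT, Phase.SWING, Unit.PERCENT),
    _sk(Side.RIGHT, Phase.SWING, Unit.PERCENT),
    _sk(Side.LEFT, Phase.STANCE, Unit.SECONDS),
    _sk(Side.RIGHT, Phase.STANCE, Unit.SECONDS),
    _sk(Side.LEFT, Phase.STANCE, Unit.PERCENT),
    _sk(Side.RIGHT, Phase.STANCE, Unit.PERCENT),
    _sk(Side.BOTH, Phase.DOUBLE_SUPPORT, Unit.SECONDS),
    _sk(Side.BOTH, Phase.DOUBLE_SUPPORT, Unit.PERCENT),
)

#: The five left/right pairs from which ratio series are formed
#: (double support has no left/right counterpart).
RATIO_PAIRS: tuple[tuple[Phase, Unit], ...] = (
    (Phase.STRIDE, Unit.SECONDS),
    (Phase.SWING, Unit.SECONDS),
    (Phase.SWING, Unit.PERCENT),
    (Phase.STANCE, Unit.SECONDS),
    (Phase.STANCE, Unit.PERCENT),
)


class ParseError(ValueError):
    """Raised for malformed gaitndd text; names the offending row/column."""


@dataclass
class GaitRecord:
    """One subject's stride-indexed gait interval series.

    All 12 series have equal length ``n_strides`` and ``elapsed_time`` is
    strictly increasing. A record is flagged invalid iff any interval
    value is <= 0 (the database marks corrupt strides with negative
    values; zeros are equally non-physical).
    """

    subject_id: str
    group: Group
    elapsed_time: np.ndarray
    series: dict[SeriesKind, np.ndarray]

    def __post_init__(self) -> None:
        self.elapsed_time = np.asarray(self.elapsed_time, dtype=float)
        self.series = {k: np.asarray(v, dtype=float) for k, v in self.series.items()}
        n = self.elapsed_time.shape[0]
        for kind, vals in self.series.items():
            if vals.shape[0] != n:
                raise ValueError(
                    f"series {kind.name} has length {vals.shape[0]}, expected {n}"
                )

    @property
    def n_strides(self) -> int:
        return int(self.elapsed_time.shape[0])

    @property
    def is_valid(self) -> bool:
        """True iff every interval value is strictly positive."""
        return all(bool(np.all(v > 0)) for v in self.series.values())


@dataclass(frozen=True)
class ValidationFinding:
    """One data-quality issue located in a record (pure report, no action)."""

    kind: str  # negative_value | zero_value | non_monotone_time | length_mismatch
    series: str
    index: int
    value: float

    def __str__(self) -> str:
        return f"{self.kind} in {self.series} at stride {self.index}: {self.value!r}"


def parse_record(stream: TextIO | str, subject_id: str, group: Group | str) -> GaitRecord:
    """Parse a 13-column whitespace-delimited gaitndd record.

    Rows with a field count other than 13 or a non-numeric field raise
    :class:`ParseError` naming the row (1-based) and column; nothing is
    silently truncated. The parser is name-agnostic: subject id and group
    come from the caller (by convention, from the file name, e.g.
    ``als1``, ``control16``).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    group = Group(group)

    rows: list[list[float]] = []
    for lineno, line in enumerate(stream, start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 13:
            raise ParseError(
                f"row {lineno}: expected 13 fields, found {len(fields)}"
            )
        values = []
        for col, tok in enumerate(fields, start=1):
            try:
                values.append(float(tok))
            except ValueError as exc:
                raise ParseError(
                    f"row {lineno}, column {col}: not a number: {tok!r}"
                ) from exc
        rows.append(values)
    if not rows:
        raise ParseError("empty record: no data rows")

    arr = np.asarray(rows, dtype=float)
    series = {kind: arr[:, i + 1].copy() for i, kind in enumerate(SERIES_COLUMNS)}
    return GaitRecord(
        subject_id=subject_id, group=group, elapsed_time=arr[:, 0].copy(), series=series
    )


def read_record(path, subject_id: str, group: Group | str) -> GaitRecord:
    """Parse a gaitndd record from a file path."""
    with open(path, "r") as fh:
        return parse_record(fh, subject_id, group)


def write_record(rec: GaitRecord, stream: TextIO) -> None:
    """Write a record back to the 13-column whitespace layout (6 decimals)."""
    cols = [rec.elapsed_time] + [rec.series[k] for k in SERIES_COLUMNS]
    mat = np.column_stack(cols)
    for row in mat:
        stream.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def validate_record(rec: GaitRecord) -> list[ValidationFinding]:
    """Report data-quality findings; the exclusion decision is the caller's.

    Finding kinds: ``negative_value`` (interval < 0, the database's marker
    for corrupt strides), ``zero_value`` (interval == 0), ``non_monotone_time``
    (elapsed time not strictly increasing), ``length_mismatch`` (construction
    normally prevents this; reported defensively for hand-built records).
    """
    findings: list[ValidationFinding] = []
    n = rec.n_strides
    for kind in SERIES_COLUMNS:
        vals = rec.series.get(kind)
        if vals is None:
            findings.append(ValidationFinding("length_mismatch", kind.name, -1, float("nan")))
            continue
        if vals.shape[0] != n:
            findings.append(
                ValidationFinding("length_mismatch", kind.name, -1, float(vals.shape[0]))
            )
        for idx in np.flatnonzero(vals < 0):
            findings.append(ValidationFinding("negative_value", kind.name, int(idx), float(vals[idx])))
        for idx in np.flatnonzero(vals == 0):
            findings.append(ValidationFinding("zero_value", kind.name, int(idx), 0.0))
    dt = np.diff(rec.elapsed_time)
    for idx in np.flatnonzero(dt <= 0):
        findings.append(
            ValidationFinding(
                "non_monotone_time", "elapsed_time", int(idx + 1), float(rec.elapsed_time[idx + 1])
            )
        )
    return findings


def write_features_csv(
    rows: Sequence[Mapping[str, object]],
    stream: TextIO,
    fieldnames: Sequence[str] | None = None,
) -> None:
    """Write a feature/summary table as RFC-4180-style CSV with header.

    All rows must share one schema (same keys); heterogeneous rows are an
    error. An empty table emits the header only, which requires
    ``fieldnames``.
    """
    rows = list(rows)
    if not rows:
        if fieldnames is None:
            raise ValueError("empty table needs explicit fieldnames for the header")
        stream.write(",".join(fieldnames) + "\n")
        return
    schema = list(fieldnames) if fieldnames is not None else list(rows[0].keys())
    for i, r in enumerate(rows, start=1):
        if list(r.keys()) != schema:
            raise ValueError(f"row {i} schema {list(r.keys())} != {schema}")
    pd.DataFrame(rows, columns=schema).to_csv(stream, index=False, lineterminator="\n")


def read_features_csv(stream: TextIO | str) -> pd.DataFrame:
    """Round-trip reader for :func:`write_features_csv` output."""
    return pd.read_csv(stream)
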