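"""Micrometeorological time series: data model, CSV I/O, validation, summaries.

A series is an ordered set of timestamped weather observations — air
temperature (``ta_c``), relative humidity (``rh_pct``), wind speed
(``ws_ms``), global solar radiation (``sr_wm2``) and, optionally,
black-globe temperature (``tg_c``) and ground-surface temperature
(``ts_c``) — as a portable weather station and globe thermometer would
log them on a playing field.  Temperatures are carried in degrees
Celsius throughout; Fahrenheit exists only inside the heat-index
regression and in explicit conversions.

Timestamps must be strictly increasing.  Duplicate or out-of-order rows
are an error, never silently resampled, and missing optional columns
stay missing: downstream models that need them fail loudly rather than
impute.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MicrometRecord",
    "MicrometSeries",
    "SeriesFormatError",
    "SeriesValidationError",
    "read_series",
    "write_series",
    "summarize",
    "CANONICAL_COLUMNS",
]

#: canonical CSV column order; the first five are mandatory
CANONICAL_COLUMNS = ("timestamp", "ta_c", "rh_pct", "ws_ms", "sr_wm2", "tg_c", "ts_c")
MANDATORY_COLUMNS = CANONICAL_COLUMNS[:5]
OPTIONAL_COLUMNS = CANONICAL_COLUMNS[5:]

#: physical bounds used in validation: variable -> (low, high), inclusive
_BOUNDS = {
    "ta_c": (-60.0, 60.0),
    "rh_pct": (0.0, 100.0),
    "ws_ms": (0.0, np.inf),
    "sr_wm2": (0.0, np.inf),
}


class SeriesFormatError(ValueError):
    """Raised when a CSV file cannot be interpreted as a micromet series."""


class SeriesValidationError(ValueError):
    """Raised when parsed values violate the physical invariants."""


@dataclass(frozen=True)
class MicrometRecord:
    """One timestamped observation of the micrometeorological variables."""

    timestamp: pd.Timestamp
    ta_c: float
    rh_pct: float
    ws_ms: float
    sr_wm2: float
    tg_c: float | None = None
    ts_c: float | None = None


@dataclass
class MicrometSeries:
    """An ordered, validated micromet time series backed by a DataFrame.

    Parameters
    ----------
    frame:
        DataFrame with the canonical columns.  Optional columns may be
        absent entirely or present for every row; a mixed column (some
        NaN) is rejected.
    interval_s:
        Nominal sampling interval in seconds (the loggers this emulates
        run at a fixed 10-s cadence).
    metadata:
        Free-form provenance strings (generator seed, site coordinates,
        instrument notes).
    """

    frame: pd.DataFrame
    interval_s: float = 10.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.interval_s <= 0:
            raise SeriesValidationError(f"interval_s must be positive, got {self.interval_s}")
        self.frame = _validate_frame(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> list[MicrometRecord]:
        out = []
        for row in self.frame.itertuples(index=False):
            out.append(
                MicrometRecord(
                    timestamp=row.timestamp,
                    ta_c=row.ta_c,
                    rh_pct=row.rh_pct,
                    ws_ms=row.ws_ms,
                    sr_wm2=row.sr_wm2,
                    tg_c=_opt(getattr(row, "tg_c", None)),
                    ts_c=_opt(getattr(row, "ts_c", None)),
                )
            )
        return out

    def has(self, column: str) -> bool:
        """True when *column* is present (for optional columns: for all rows)."""
        return column in self.frame.columns


def _opt(v):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return float(v)


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    if len(frame) == 0:
        raise SeriesValidationError("series must contain at least one record")
    for col in MANDATORY_COLUMNS:
        if col not in frame.columns:
            raise SeriesFormatError(f"missing mandatory column: {col!r}")

    frame = frame.reset_index(drop=True)
    ts = pd.to_datetime(frame["timestamp"])
    if ts.isna().any():
        bad = int(ts.index[ts.isna()][0]) + 1
        raise SeriesValidationError(f"unparseable timestamp on data row {bad}")
    diffs = ts.diff().dropna()
    if (diffs <= pd.Timedelta(0)).any():
        bad = int(diffs.index[diffs <= pd.Timedelta(0)][0]) + 1
        raise SeriesValidationError(
            f"timestamps must be strictly increasing; violation at data row {bad}"
        )
    frame = frame.assign(timestamp=ts)

    for col in ("ta_c", "rh_pct", "ws_ms", "sr_wm2"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.isna().any():
            bad = int(vals.index[vals.isna()][0]) + 1
            raise SeriesValidationError(f"non-numeric {col} on data row {bad}")
        lo, hi = _BOUNDS[col]
        out_of_range = (vals < lo) | (vals > hi)
        if out_of_range.any():
            bad = int(vals.index[out_of_range][0]) + 1
            raise SeriesValidationError(
                f"{col}={vals[bad - 1]} out of range [{lo}, {hi}] on data row {bad}"
            )
        frame[col] = vals.astype(float)

    # optional columns: either fully present or dropped; partial is ambiguous
    for col in OPTIONAL_COLUMNS:
        if col not in frame.columns:
            continue
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.isna().all():
            frame = frame.drop(columns=[col])
        elif vals.isna().any():
            bad = int(vals.index[vals.isna()][0]) + 1
            raise SeriesValidationError(
                f"optional column {col} present but missing on data row {bad}; "
                "optional variables must be present for all records or none"
            )
        else:
            frame[col] = vals.astype(float)

    cols = [c for c in CANONICAL_COLUMNS if c in frame.columns]
    return frame[cols]


def _map_columns(columns: Sequence[str]) -> dict[str, str]:
    """Case-insensitive mapping of file headers onto canonical names."""
    mapping = {}
    canon = {c.lower(): c for c in CANONICAL_COLUMNS}
    for col in columns:
        key = str(col).strip().lower()
        if key in canon:
            mapping[col] = canon[key]
    return mapping


def read_series(path, dialect: str = "generic", interval_s: float = 10.0) -> MicrometSeries:
    """Read a micromet CSV file.

    ``dialect="generic"`` expects a plain header row; ``dialect="logger"``
    tolerates one free-text preamble line and a unit row directly under
    the header (both are skipped), as logger CSV exports commonly carry.
    Header matching is case-insensitive on the canonical names.
    """
    if dialect not in ("generic", "logger"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'generic' or 'logger'")
    with open(path, "r", newline="") as fh:
        text = fh.read()
    lines = text.splitlines()
    if dialect == "logger":
        if len(lines) < 2:
            raise SeriesFormatError("logger file too short for preamble + header")
        lines = lines[1:]  # drop preamble
    raw = pd.read_csv(io.StringIO("\n".join(lines)), dtype=str, skipinitialspace=True)
    if dialect == "logger" and len(raw) > 0:
        # unit row: first data row where the timestamp cell is not parseable
        first = raw.iloc[0, 0]
        if pd.isna(pd.to_datetime(first, errors="coerce")):
            raw = raw.iloc[1:].reset_index(drop=True)
    raw = raw.rename(columns=_map_columns(raw.columns))
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SeriesFormatError(f"missing mandatory column: {missing[0]!r}")
    raw = raw[[c for c in CANONICAL_COLUMNS if c in raw.columns]]
    return MicrometSeries(frame=raw, interval_s=interval_s, metadata={"source": str(path)})


def write_series(series: MicrometSeries, path) -> None:
    """Write a series as CSV: canonical header, ISO 8601 timestamps,
    missing optional columns as empty cells."""
    frame = series.frame.copy()
    frame["timestamp"] = frame["timestamp"].map(lambda t: t.isoformat())
    for col in OPTIONAL_COLUMNS:
        if col not in frame.columns:
            frame[col] = ""
    frame = frame[list(CANONICAL_COLUMNS)]
    frame.to_csv(path, index=False)


def summarize(
    series: MicrometSeries | pd.DataFrame,
    variables: Iterable[str],
    decimals: int | None = 1,
) -> pd.DataFrame:
    """Per-variable max / min / arithmetic mean over the series.

    Mirrors the layout of a field-session summary table (rows Max, Min,
    Mean; one column per variable), reported at 1-decimal precision by
    default; pass ``decimals=None`` for full precision.
    """
    frame = series.frame if isinstance(series, MicrometSeries) else series
    variables = list(variables)
    for v in variables:
        if v not in frame.columns:
            raise KeyError(f"unknown variable {v!r}; available: {list(frame.columns)}")
    data = {
        v: [frame[v].max(), frame[v].min(), frame[v].mean()] for v in variables
    }
    table = pd.DataFrame(data, index=["Max", "Min", "Mean"])
    if decimals is not None:
        table = table.round(decimals)
    return table
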