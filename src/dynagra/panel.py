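"""Monitoring panels and correlation records: the package's data model and I/O.

A :class:`MonitoringPanel` is an hourly (station, variable, time) value cube
backed by a pandas DataFrame with a ``DatetimeIndex`` of strictly increasing,
uniformly spaced hourly timestamps and a two-level column index
``(station, variable)``.  Gaps in the native data appear as explicit NaN
entries after loading, never as absent rows.  Station coordinates (distance
and bearing to a designated central station) are carried as metadata only —
no spatial weighting is ever applied to the correlation computations.

Input is long-format (tidy) delimited text with one row per
(timestamp, station, variable, value) observation; station and variable are
both first-class axes of the analysis, which a wide layout cannot express
without privileging one of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FrequencyError,
    LookupError_,
    PanelIntegrityError,
    ShapeError,
    TimestampParseError,
)

#: Closed enumeration of correlation methods.
METHODS = ("static", "fsw_gra", "asw_pc", "asw_gra")

#: Methods whose degree lives on the grey-relational (0, 1] scale.
GRA_METHODS = ("static", "fsw_gra", "asw_gra")


@dataclass(frozen=True)
class StationInfo:
    """Metadata for one monitoring station.

    distance_m / bearing_deg are relative to the network's central station
    (bearing in degrees clockwise from north); both optional.
    """

    station: str
    distance_m: float | None = None
    bearing_deg: float | None = None


@dataclass(frozen=True)
class ColumnSpec:
    """Mapping from file columns to the canonical tidy schema."""

    timestamp: str = "timestamp"
    station: str = "station"
    variable: str = "variable"
    value: str = "value"


class MonitoringPanel:
    """Hourly stations x variables x time value cube.

    Parameters
    ----------
    values
        DataFrame indexed by hourly timestamps with MultiIndex columns
        ``(station, variable)``; missing observations are NaN.
    stations
        Optional metadata records; stations present in `values` but absent
        here get bare entries.
    units
        Optional mapping variable name -> unit string.
    attrs
        Free-form metadata (e.g. synthetic ground truth).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        stations: Sequence[StationInfo] | None = None,
        units: dict[str, str] | None = None,
        attrs: dict | None = None,
    ) -> None:
        if not isinstance(values.index, pd.DatetimeIndex):
            raise PanelIntegrityError("panel index must be a DatetimeIndex")
        if values.columns.nlevels != 2:
            raise PanelIntegrityError(
                "panel columns must be a (station, variable) MultiIndex"
            )
        idx = values.index
        if len(idx) > 1:
            deltas = np.diff(idx.asi8)
            if not (deltas > 0).all():
                raise PanelIntegrityError("timestamps must be strictly increasing")
            if not (deltas == 3_600_000_000_000).all():
                raise FrequencyError(
                    "timestamps must lie on a uniform 1-hour grid; "
                    "gaps must be explicit missing values"
                )
        if values.columns.duplicated().any():
            raise PanelIntegrityError("duplicate (station, variable) columns")
        self.values = values.sort_index(axis=1)
        meta = {s.station: s for s in (stations or [])}
        self.stations: dict[str, StationInfo] = {
            s: meta.get(s, StationInfo(s)) for s in self.station_ids
        }
        self.units: dict[str, str] = dict(units or {})
        self.attrs: dict = dict(attrs or {})

    # -- axes ---------------------------------------------------------------

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.values.index

    @property
    def station_ids(self) -> list[str]:
        return list(self.values.columns.get_level_values(0).unique())

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns.get_level_values(1).unique())

    @property
    def n_hours(self) -> int:
        return len(self.values.index)

    # -- access -------------------------------------------------------------

    def series(self, station: str, variable: str) -> pd.Series:
        """Return one (station, variable) series, NaN where missing."""
        key = (station, variable)
        if key not in self.values.columns:
            raise LookupError_(
                f"series ({station!r}, {variable!r}) not present in panel"
            )
        return self.values[key]

    def array(self, station: str, variable: str) -> np.ndarray:
        return self.series(station, variable).to_numpy(dtype=float)

    # -- I/O ----------------------------------------------------------------

    def to_tidy_frame(self) -> pd.DataFrame:
        """Long-format (timestamp, station, variable, value) frame; NaN rows kept."""
        long = self.values.stack([0, 1], future_stack=True).rename("value").reset_index()
        long.columns = ["timestamp", "station", "variable", "value"]
        return long

    def write(self, path: str | Path) -> None:
        """Write the panel as tidy delimited text (CSV/TSV by extension)."""
        sep = _sep_for(path)
        self.to_tidy_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_panel(path: str | Path, spec: ColumnSpec | None = None) -> MonitoringPanel:
    """Load a tidy monitoring file into a :class:`MonitoringPanel`.

    The hour grid between the earliest and latest timestamp is completed, with
    explicit NaN markers where observations are absent.  Duplicate
    (timestamp, station, variable) cells are rejected, and timestamps that do
    not fall on exact hours raise :class:`FrequencyError`.
    """
    spec = spec or ColumnSpec()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    for col in (spec.timestamp, spec.station, spec.variable, spec.value):
        if col not in raw.columns:
            raise PanelIntegrityError(f"required column {col!r} missing from {path}")

    ts = pd.to_datetime(raw[spec.timestamp], errors="coerce", format="mixed")
    if ts.isna().any():
        row = int(ts.isna().idxmax())
        raise TimestampParseError(
            f"malformed timestamp {raw[spec.timestamp].iloc[row]!r} at row {row}"
        )
    if not (ts == ts.dt.floor("h")).all():
        bad = ts[ts != ts.dt.floor("h")].iloc[0]
        raise FrequencyError(
            f"timestamp {bad} is not on the hourly grid and cannot be snapped"
        )
    if getattr(ts.dt, "tz", None) is not None:
        ts = ts.dt.tz_localize(None)

    tidy = pd.DataFrame(
        {
            "timestamp": ts,
            "station": raw[spec.station].astype(str),
            "variable": raw[spec.variable].astype(str),
            "value": pd.to_numeric(raw[spec.value], errors="coerce"),
        }
    )
    dup = tidy.duplicated(subset=["timestamp", "station", "variable"], keep=False)
    if dup.any():
        t0, s0, v0 = tidy.loc[dup.idxmax(), ["timestamp", "station", "variable"]]
        raise PanelIntegrityError(
            f"duplicate cell at ({t0}, {s0!r}, {v0!r}); tidy input must be unique"
        )

    wide = tidy.pivot(index="timestamp", columns=["station", "variable"], values="value")
    full = pd.date_range(wide.index.min(), wide.index.max(), freq="h")
    wide = wide.reindex(full)
    wide.index.name = "timestamp"
    return MonitoringPanel(wide)


# -- correlation records ----------------------------------------------------


@dataclass(frozen=True)
class CorrelationRecord:
    """One dynamic-correlation observation.

    ``degree`` holds the correlation degree r_k: for the GRA-based methods it
    lies in (0, 1]; for the partial-correlation contrast in [-1, 1].
    ``window_length`` is the decided trailing-window length (None for the
    static whole-period method).
    """

    time: pd.Timestamp
    object_station: str
    object_variable: str
    associated_station: str
    associated_variable: str
    method: str
    window_length: int | None
    degree: float

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ShapeError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if (self.object_station, self.object_variable) == (
            self.associated_station,
            self.associated_variable,
        ):
            raise ShapeError("object and associated series must differ")
        if self.window_length is not None and self.window_length < 1:
            raise ShapeError("window_length must be a positive integer")
        d = self.degree
        if self.method in GRA_METHODS:
            if not (0.0 < d <= 1.0 + 1e-12):
                raise ShapeError(f"GRA degree {d} outside (0, 1]")
        elif not (-1.0 - 1e-12 <= d <= 1.0 + 1e-12):
            raise ShapeError(f"partial-correlation degree {d} outside [-1, 1]")

    @property
    def object(self) -> tuple[str, str]:
        return (self.object_station, self.object_variable)

    @property
    def associated(self) -> tuple[str, str]:
        return (self.associated_station, self.associated_variable)


_RECORD_COLUMNS = [
    "time",
    "object_station",
    "object_variable",
    "associated_station",
    "associated_variable",
    "method",
    "window_length",
    "degree",
]


def records_to_frame(records: Iterable[CorrelationRecord]) -> pd.DataFrame:
    rows = [
        (
            r.time,
            r.object_station,
            r.object_variable,
            r.associated_station,
            r.associated_variable,
            r.method,
            r.window_length,
            r.degree,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[CorrelationRecord]:
    out = []
    for row in frame.itertuples(index=False):
        wl = row.window_length
        wl = None if wl is None or (isinstance(wl, float) and math.isnan(wl)) else int(wl)
        out.append(
            CorrelationRecord(
                time=pd.Timestamp(row.time),
                object_station=str(row.object_station),
                object_variable=str(row.object_variable),
                associated_station=str(row.associated_station),
                associated_variable=str(row.associated_variable),
                method=str(row.method),
                window_length=wl,
                degree=float(row.degree),
            )
        )
    return out


def write_correlations(records: Sequence[CorrelationRecord], path: str | Path) -> None:
    """Write records as delimited text; degrees keep 17 significant digits so a
    read-back reproduces them bit-for-bit."""
    frame = records_to_frame(records)
    frame.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


def read_correlations(path: str | Path) -> list[CorrelationRecord]:
    frame = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    missing = [c for c in _RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise ShapeError(f"correlation file {path} missing columns {missing}")
    return frame_to_records(frame)
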