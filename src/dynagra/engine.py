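"""Dynamic spatio-temporal correlation engine.

The three analysis modes share one time recurrence.  At each hourly time
point t with at least L0 valid object values before it, the adaptive window
length L is decided from the L0 most recent valid values of the object
series strictly before t; the correlation degree is then computed on the
trailing L values ending at (and including) t.  Earlier time points produce
no records.  Because the decision and the window only ever look backwards,
the record at time t never depends on data after t.

Modes:

* variable mode — one station, one object pollutant against a candidate set
  of variables, scored jointly (the two-level extrema of the relational
  coefficient run over the whole candidate set, as the method defines them);
* point mode — one pollutant across stations, scored pairwise so each
  station's degree is independent of which other candidates were requested;
* cross mode — arbitrary (station, variable) pairs, scored pairwise.

Missing values: the trailing window is taken over calendar hours; rows where
any involved series is missing are dropped, and the time step is skipped
(with a logged warning) when more than ``max_gap_fraction`` of the window is
lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import LookupError_, NotComputableError, ShapeError
from .gra import grey_relational_degrees, pairwise_degree
from .panel import CorrelationRecord, MonitoringPanel
from .window import WindowConfig, adapt_window_length

logger = logging.getLogger("dynagra")

Key = tuple[str, str]  # (station, variable)


def decide_window_at(values: np.ndarray, i: int, wconfig: WindowConfig) -> int | None:
    """Adaptive length at 0-based index ``i`` from the L0 most recent valid
    values strictly before ``i``; None when history is insufficient."""
    hist = values[:i]
    valid = hist[~np.isnan(hist)]
    if valid.size < wconfig.L0:
        return None
    return adapt_window_length(valid[-wconfig.L0 :], wconfig).L


def _decide(panel_arrays: dict[Key, np.ndarray], keys: Sequence[Key], i: int,
            config: RunConfig, wconfig: WindowConfig) -> int | None:
    """Window decision for one step: object-only or pairwise maximum."""
    if config.window_mode == "object":
        keys = keys[:1]
    lengths = []
    for k in keys:
        L = decide_window_at(panel_arrays[k], i, wconfig)
        if L is None:
            return None
        lengths.append(L)
    return max(lengths)


def _window_rows(
    arrays: list[np.ndarray], i: int, L: int, max_gap_fraction: float
) -> list[np.ndarray] | None:
    """Trailing window [i-L+1, i] across the given series, rows with any
    missing value dropped; None when the gap budget is exceeded."""
    lo = max(0, i - L + 1)
    cols = [a[lo : i + 1] for a in arrays]
    mask = ~np.logical_or.reduce([np.isnan(c) for c in cols])
    span = i + 1 - lo
    kept = int(mask.sum())
    if kept < 2 or (span - kept) / span > max_gap_fraction:
        return None
    if kept == span:
        return cols
    return [c[mask] for c in cols]


def _check_keys(panel: MonitoringPanel, keys: Sequence[Key]) -> None:
    for st, var in keys:
        panel.series(st, var)  # raises LookupError_ with a precise message


def _dynamic_series(
    panel: MonitoringPanel,
    object_key: Key,
    associated_keys: Sequence[Key],
    config: RunConfig,
    joint: bool,
) -> list[CorrelationRecord]:
    _check_keys(panel, [object_key, *associated_keys])
    if object_key in associated_keys:
        raise ShapeError(f"object {object_key} also listed among candidates")
    arrays = {k: panel.array(*k) for k in (object_key, *associated_keys)}
    wconfig = config.window.resolved(panel.n_hours)
    times = panel.timestamps
    records: list[CorrelationRecord] = []

    for i in range(wconfig.L0, panel.n_hours):
        L = _decide(arrays, [object_key, *associated_keys], i, config, wconfig)
        if L is None:
            continue
        L = min(L, i + 1)  # early steps: only i+1 hours of history exist
        if joint:
            rows = _window_rows(
                [arrays[object_key]] + [arrays[k] for k in associated_keys],
                i, L, config.max_gap_fraction,
            )
            if rows is None:
                logger.warning("gap budget exceeded at %s; step skipped", times[i])
                continue
            degrees = grey_relational_degrees(
                rows[0], np.vstack(rows[1:]), config.rho, config.normalization
            )
            pairs = zip(associated_keys, degrees)
        else:
            pairs = []
            for k in associated_keys:
                rows = _window_rows(
                    [arrays[object_key], arrays[k]], i, L, config.max_gap_fraction
                )
                if rows is None:
                    logger.warning(
                        "gap budget exceeded at %s for %s; pair skipped", times[i], k
                    )
                    continue
                pairs.append(
                    (k, pairwise_degree(rows[0], rows[1], config.rho, config.normalization))
                )
        for k, degree in pairs:
            records.append(
                CorrelationRecord(
                    time=times[i],
                    object_station=object_key[0],
                    object_variable=object_key[1],
                    associated_station=k[0],
                    associated_variable=k[1],
                    method="asw_gra",
                    window_length=L,
                    degree=float(degree),
                )
            )
    return records


def variable_correlation_series(
    panel: MonitoringPanel,
    station: str,
    object_variable: str,
    candidate_variables: Sequence[str],
    config: RunConfig | None = None,
) -> list[CorrelationRecord]:
    """Dynamic degrees of one station's object pollutant against candidate
    variables, scored jointly over the candidate set."""
    config = config or RunConfig()
    if object_variable in candidate_variables:
        raise ShapeError("object variable must not appear among candidates")
    return _dynamic_series(
        panel,
        (station, object_variable),
        [(station, v) for v in candidate_variables],
        config,
        joint=True,
    )


def point_correlation_series(
    panel: MonitoringPanel,
    variable: str,
    object_station: str,
    candidate_stations: Sequence[str],
    config: RunConfig | None = None,
    joint: bool = False,
) -> list[CorrelationRecord]:
    """Dynamic degrees of one pollutant at the object station against the
    same pollutant at candidate stations.

    By default each station is scored pairwise so its degree does not depend
    on which other candidates were requested.  ``joint=True`` shares the
    two-level extrema across the candidate set instead, which is the form
    that discriminates coupling *strength* between stations (the pairwise
    coefficient only sees deviations relative to the pair's own maximum and
    is nearly scale-free); use it when ranking stations against each other.
    """
    config = config or RunConfig()
    if object_station in candidate_stations:
        raise ShapeError("object station must not appear among candidates")
    return _dynamic_series(
        panel,
        (object_station, variable),
        [(s, variable) for s in candidate_stations],
        config,
        joint=joint,
    )


def cross_dimension_series(
    panel: MonitoringPanel,
    pairs: Sequence[tuple[Key, Key]],
    config: RunConfig | None = None,
) -> list[CorrelationRecord]:
    """Dynamic degrees for explicit (station, variable) x (station, variable)
    pairs, e.g. PM2.5 at one point against CO at another."""
    config = config or RunConfig()
    records: list[CorrelationRecord] = []
    for obj, assoc in pairs:
        if obj == assoc:
            raise ShapeError(f"pair {obj} vs {assoc}: object equals associated")
        records.extend(_dynamic_series(panel, obj, [assoc], config, joint=False))
    return records


@dataclass(frozen=True)
class CrossPointMatrix:
    """All-station pairwise degrees of one pollutant at one time point.

    ``degrees`` is a symmetric DataFrame with unit diagonal, labelled by
    station id; ``strongest_pair`` names the off-diagonal maximum — the
    strongest inter-station interaction at that moment.
    """

    time: pd.Timestamp
    variable: str
    degrees: pd.DataFrame

    @property
    def strongest_pair(self) -> tuple[str, str, float]:
        m = self.degrees.to_numpy(copy=True)
        np.fill_diagonal(m, -np.inf)
        p, q = np.unravel_index(np.argmax(m), m.shape)
        ids = list(self.degrees.index)
        return ids[p], ids[q], float(m[p, q])


def cross_point_matrix(
    panel: MonitoringPanel,
    variable: str,
    time: pd.Timestamp | str,
    config: RunConfig | None = None,
) -> CrossPointMatrix:
    """Pairwise degree matrix over all stations for one pollutant at ``time``.

    Each pair's window is the maximum of the two stations' adaptive
    decisions, so the matrix is symmetric by construction.
    """
    config = config or RunConfig()
    time = pd.Timestamp(time)
    times = panel.timestamps
    if time not in times:
        raise NotComputableError(f"time {time} not in panel range")
    i = int(times.get_loc(time))
    wconfig = config.window.resolved(panel.n_hours)
    stations = panel.station_ids
    arrays = {s: panel.array(s, variable) for s in stations}

    decided: dict[str, int] = {}
    for s in stations:
        L = decide_window_at(arrays[s], i, wconfig)
        if L is None:
            earliest = times[wconfig.L0] if panel.n_hours > wconfig.L0 else None
            raise NotComputableError(
                f"insufficient history for station {s!r} at {time}; "
                f"earliest computable time is {earliest}"
            )
        decided[s] = L

    n = len(stations)
    mat = np.ones((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            L = min(max(decided[stations[a]], decided[stations[b]]), i + 1)
            rows = _window_rows(
                [arrays[stations[a]], arrays[stations[b]]],
                i, L, config.max_gap_fraction,
            )
            if rows is None:
                raise NotComputableError(
                    f"gap budget exceeded for pair ({stations[a]}, {stations[b]}) at {time}"
                )
            d = pairwise_degree(rows[0], rows[1], config.rho, config.normalization)
            mat[a, b] = mat[b, a] = d
    frame = pd.DataFrame(mat, index=stations, columns=stations)
    return CrossPointMatrix(time=time, variable=variable, degrees=frame)
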