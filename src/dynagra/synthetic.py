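"""Synthetic hourly monitoring-grid scenarios.

Generates panels that emulate a small air-quality monitoring network: a
central station surrounded by satellite stations at known distances and
bearings, a handful of pollutant and meteorological variables, hourly
sampling over a study period of a few hundred hours.

The generative model is deliberately minimal — just enough structure to
exhibit the phenomena the dynamic analysis is designed to expose:

* a latent source pollutant signal S(t): AR(1) with coefficient 0.8 plus a
  diurnal sinusoid and a slower seasonal component (per season template);
* satellite-station copies of the source pollutant: alpha_p * S(t - lag_p)
  plus local AR(1) noise, with station-specific coupling strength alpha_p
  in [0, 1] and integer lag hours — the knob parameter-recovery tests rank;
* coupled pollutant variables: beta_v * S(t - lag_v) plus local noise;
* an independent nuisance pollutant (pure AR(1)), and a meteorological
  driver (diurnal sinusoid plus noise) uncorrelated with the source;
* an optional mid-series regime switch that replaces the station coupling
  map at a known hour, giving tests a ground-truth change point.

No plume physics or advection is simulated; the generator is a statistical
stand-in for a dense industrial-park sensor grid, and is labelled synthetic
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .panel import MonitoringPanel, StationInfo

__all__ = [
    "VariableSpec",
    "RegimeSwitch",
    "SyntheticScenario",
    "default_scenario",
    "generate_scenario",
    "generate_regime_switch",
]

ROLES = ("source_pollutant", "coupled_pollutant", "independent_nuisance", "meteorological_driver")

#: (diurnal amplitude, slow amplitude, slow period h, slow phase) per season
SEASON_TEMPLATES = {
    "summer": (1.0, 1.0, 120.0, 0.0),
    "winter": (0.6, 1.5, 160.0, np.pi / 2),
    "spring": (0.8, 1.2, 140.0, np.pi / 4),
}


@dataclass(frozen=True)
class VariableSpec:
    """One monitored variable and its generative role."""

    name: str
    role: str
    unit: str = "ug/m3"
    coupling: float = 0.0  # beta_v for coupled pollutants
    lag: int = 0  # hours

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}; expected {ROLES}")
        if self.lag < 0:
            raise ValidationError("lag must be >= 0 hours")
        if not (0.0 <= self.coupling <= 1.0):
            raise ValidationError("coupling must lie in [0, 1]")


@dataclass(frozen=True)
class RegimeSwitch:
    """Change of the station coupling map at a known hour index."""

    time_index: int
    station_coupling: dict[str, float]


@dataclass(frozen=True)
class SyntheticScenario:
    """Generative specification for one synthetic monitoring panel.

    ``station_coupling`` maps satellite station id -> alpha_p; the central
    station always carries the source signal itself.  ``noise_sd`` scales
    the local AR(1) noise added to every derived series.
    """

    stations: tuple[StationInfo, ...]
    central: str
    variables: tuple[VariableSpec, ...]
    station_coupling: dict[str, float]
    station_lag: dict[str, int]
    season: str = "summer"
    noise_sd: float = 0.3
    ar_coefficient: float = 0.8
    local_ar_coefficient: float = 0.5
    n_hours: int = 240
    start: str = "2016-07-11"
    seed: int = 0
    regime_switch: RegimeSwitch | None = None

    def __post_init__(self) -> None:
        ids = [s.station for s in self.stations]
        if len(set(ids)) != len(ids):
            raise ValidationError("station ids must be unique")
        if self.central not in ids:
            raise ValidationError(f"central station {self.central!r} not in grid")
        for sid, a in self.station_coupling.items():
            if sid not in ids:
                raise ValidationError(f"coupling given for unknown station {sid!r}")
            if not (0.0 <= a <= 1.0):
                raise ValidationError(f"coupling alpha for {sid!r} must lie in [0, 1]")
        for sid, lag in self.station_lag.items():
            if lag < 0:
                raise ValidationError(f"lag for {sid!r} must be >= 0")
        if self.season not in SEASON_TEMPLATES:
            raise ValidationError(f"unknown season template {self.season!r}")
        if self.n_hours < 11:
            raise ValidationError("n_hours must exceed the default window length")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.regime_switch is not None:
            t = self.regime_switch.time_index
            if not (0 < t < self.n_hours):
                raise ValidationError(
                    f"regime switch at hour {t} lies outside the series (0, {self.n_hours})"
                )

    @property
    def source_variable(self) -> str:
        for v in self.variables:
            if v.role == "source_pollutant":
                return v.name
        raise ValidationError("scenario defines no source pollutant")


def default_scenario(seed: int = 0, **overrides) -> SyntheticScenario:
    """A nine-station grid around a central station, five variables, 240 h.

    Satellite couplings decay with distance from the centre; the four named
    near stations (east/northeast/west/southeast at 500-1000 m) carry the
    strongest couplings.
    """
    stations = (
        StationInfo("HS", 0.0, None),
        StationInfo("N1", 500.0, 90.0),
        StationInfo("N2", 1000.0, 45.0),
        StationInfo("N3", 500.0, 270.0),
        StationInfo("N4", 1000.0, 135.0),
        StationInfo("N5", 500.0, 0.0),
        StationInfo("N6", 1000.0, 315.0),
        StationInfo("N7", 500.0, 180.0),
        StationInfo("N8", 1000.0, 225.0),
    )
    variables = (
        VariableSpec("PM2.5", "source_pollutant"),
        VariableSpec("PM10", "coupled_pollutant", coupling=0.9, lag=0),
        VariableSpec("CO", "coupled_pollutant", unit="mg/m3", coupling=0.6, lag=1),
        VariableSpec("TVOC", "independent_nuisance"),
        VariableSpec("temperature", "meteorological_driver", unit="degC"),
    )
    coupling = {
        "N1": 0.9, "N2": 0.6, "N3": 0.8, "N4": 0.5,
        "N5": 0.7, "N6": 0.4, "N7": 0.6, "N8": 0.3,
    }
    lags = {s: (0 if info.distance_m <= 500 else 1)
            for s, info in ((st.station, st) for st in stations) if s != "HS"}
    base = SyntheticScenario(
        stations=stations,
        central="HS",
        variables=variables,
        station_coupling=coupling,
        station_lag=lags,
        seed=seed,
    )
    return replace(base, **overrides) if overrides else base


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float, burn: int = 48) -> np.ndarray:
    e = rng.normal(0.0, sd, n + burn)
    out = np.empty(n + burn)
    out[0] = e[0]
    for t in range(1, n + burn):
        out[t] = phi * out[t - 1] + e[t]
    return out[burn:]


def _lagged(x: np.ndarray, lag: int) -> np.ndarray:
    if lag == 0:
        return x
    out = np.empty_like(x)
    out[lag:] = x[:-lag]
    out[:lag] = x[0]  # hold the first value; keeps series fully defined
    return out


def generate_scenario(scenario: SyntheticScenario) -> MonitoringPanel:
    """Deterministically render a scenario into a monitoring panel."""
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_hours
    t = np.arange(n, dtype=float)
    diurnal_amp, slow_amp, slow_period, slow_phase = SEASON_TEMPLATES[scenario.season]
    seasonal = diurnal_amp * np.sin(2 * np.pi * t / 24.0) + slow_amp * np.sin(
        2 * np.pi * t / slow_period + slow_phase
    )
    source = _ar1(rng, n, scenario.ar_coefficient, 1.0) + seasonal

    # per-station coupling profile over time (regime switch = step change)
    def alpha_profile(sid: str) -> np.ndarray:
        a0 = scenario.station_coupling.get(sid, 0.0)
        prof = np.full(n, a0)
        rs = scenario.regime_switch
        if rs is not None and sid in rs.station_coupling:
            prof[rs.time_index :] = rs.station_coupling[sid]
        return prof

    columns: dict[tuple[str, str], np.ndarray] = {}
    for st in scenario.stations:
        sid = st.station
        is_central = sid == scenario.central
        lag_p = 0 if is_central else scenario.station_lag.get(sid, 0)
        alpha_p = None if is_central else alpha_profile(sid)
        for v in scenario.variables:
            if v.role == "source_pollutant":
                if is_central:
                    series = source
                else:
                    series = alpha_p * _lagged(source, lag_p) + _ar1(
                        rng, n, scenario.local_ar_coefficient, scenario.noise_sd
                    )
            elif v.role == "coupled_pollutant":
                base = v.coupling * _lagged(source, v.lag + lag_p)
                if not is_central:
                    base = base * alpha_p
                series = base + _ar1(
                    rng, n, scenario.local_ar_coefficient, scenario.noise_sd
                )
            elif v.role == "independent_nuisance":
                series = _ar1(rng, n, scenario.ar_coefficient, 1.0)
            else:  # meteorological_driver
                series = diurnal_amp * np.sin(2 * np.pi * (t + 3.0) / 24.0) + rng.normal(
                    0.0, scenario.noise_sd, n
                )
            columns[(sid, v.name)] = series

    index = pd.date_range(scenario.start, periods=n, freq="h")
    frame = pd.DataFrame(columns, index=index)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["station", "variable"])
    frame.index.name = "timestamp"
    attrs = {
        "synthetic": True,
        "seed": scenario.seed,
        "season": scenario.season,
        "station_coupling": dict(scenario.station_coupling),
        "station_lag": dict(scenario.station_lag),
    }
    if scenario.regime_switch is not None:
        attrs["regime_switch"] = {
            "time_index": scenario.regime_switch.time_index,
            "time": str(index[scenario.regime_switch.time_index]),
            "station_coupling": dict(scenario.regime_switch.station_coupling),
        }
    return MonitoringPanel(
        frame,
        stations=list(scenario.stations),
        units={v.name: v.unit for v in scenario.variables},
        attrs=attrs,
    )


def generate_regime_switch(scenario: SyntheticScenario) -> MonitoringPanel:
    """Render a scenario whose coupling map changes mid-series.

    Identical to :func:`generate_scenario` but requires ``regime_switch`` to
    be set; the ground-truth change point lands in ``panel.attrs``.
    """
    if scenario.regime_switch is None:
        raise ValidationError("scenario has no regime_switch set")
    return generate_scenario(scenario)
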