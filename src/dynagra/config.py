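"""Run configuration: window, GRA and engine options, YAML round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .gra import NORMALIZATIONS
from .panel import ColumnSpec
from .window import WindowConfig

WINDOW_MODES = ("object", "pairwise_max")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one analysis run.

    Attributes
    ----------
    window
        Adaptive-window parameters (default length, clamps).
    rho
        GRA resolution ratio, 0 < rho < 1.
    normalization
        Sequence normalisation before GRA: minmax / initial_value / none.
    max_gap_fraction
        Largest fraction of missing rows tolerated inside one correlation
        window before the time step is skipped.
    window_mode
        'object': window decided from the object series alone;
        'pairwise_max': the max of the two series' decided lengths.
    fixed_window
        Window length for the fixed-sliding-window contrast method (hours).
    columns
        Column mapping for tidy input files.
    seed
        Seed for synthetic-scenario generation.
    """

    window: WindowConfig = field(default_factory=WindowConfig)
    rho: float = 0.5
    normalization: str = "minmax"
    max_gap_fraction: float = 0.10
    window_mode: str = "object"
    fixed_window: int = 24
    columns: ColumnSpec = field(default_factory=ColumnSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.rho < 1.0):
            raise ConfigError(f"rho={self.rho} violates 0 < rho < 1")
        if self.normalization not in NORMALIZATIONS:
            raise ConfigError(
                f"normalization {self.normalization!r} not in {NORMALIZATIONS}"
            )
        if not (0.0 <= self.max_gap_fraction < 1.0):
            raise ConfigError("max_gap_fraction must lie in [0, 1)")
        if self.window_mode not in WINDOW_MODES:
            raise ConfigError(f"window_mode {self.window_mode!r} not in {WINDOW_MODES}")
        if self.fixed_window < 2:
            raise ConfigError("fixed_window must be >= 2")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        win = data.pop("window", {})
        if isinstance(win, dict):
            win = WindowConfig(
                L0=int(win.get("default_length", 10)),
                Lmin=int(win.get("min_length", 10)),
                Lmax=(int(win["max_length"]) if "max_length" in win else None),
                max_length_fraction=float(win.get("max_length_fraction", 0.10)),
            )
        gra = data.pop("gra", {})
        cols = data.pop("io", {})
        spec = ColumnSpec(
            timestamp=cols.get("timestamp", "timestamp"),
            station=cols.get("station", "station"),
            variable=cols.get("variable", "variable"),
            value=cols.get("value", "value"),
        )
        engine = data.pop("engine", {})
        return cls(
            window=win,
            rho=float(gra.get("rho", data.pop("rho", 0.5))),
            normalization=gra.get("normalization", data.pop("normalization", "minmax")),
            max_gap_fraction=float(
                engine.get("max_gap_fraction", data.pop("max_gap_fraction", 0.10))
            ),
            window_mode=engine.get("window_mode", data.pop("window_mode", "object")),
            fixed_window=int(engine.get("fixed_window", data.pop("fixed_window", 24))),
            columns=spec,
            seed=int(data.pop("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if data is not None and not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data or {})
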