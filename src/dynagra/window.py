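"""Entropy-based adaptive sliding-window length selection.

The window length used for each dynamic correlation step is decided from the
most recent segment of the object series: the segment's point-to-point
fluctuations are mapped to a probability distribution, whose Shannon entropy
measures how evenly the recent change is spread over time.  Smooth recent
data (high, even entropy) lengthen the window to pool more history; spiky
recent data (entropy concentrated in a few jumps) shorten it so the analysis
reacts to instantaneous behaviour.

Pipeline, for a trailing segment d_1..d_{L0} with mean m:

    z_i   = |d_{i+1} - d_i| / m                  (fluctuation scalars)
    p_i   = z_i / sum(z)                         (fluctuation probabilities)
    H     = -sum p_i log2 p_i                    (fluctuation entropy, bits)
    s     = H / log2(L0)                         (adjustment proportion)
    s_min = min p_i,  s_max = max p_i            (stability thresholds)

    L = L0            if s_min < s < s_max
    L = round(L0 / s) if s >= s_max
    L = round(s * L0) if s <= s_min

finally clamped into [Lmin, Lmax].  The reference entropy is log2(L0) even
though only L0-1 probabilities exist, so s < 1 strictly; see docs/methods.md
for the degenerate-case conventions (zero mean, constant segment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError, DomainError, LengthError

__all__ = [
    "WindowConfig",
    "WindowDecision",
    "fluctuation_scalars",
    "fluctuation_probabilities",
    "fluctuation_entropy",
    "adapt_window_length",
]


@dataclass(frozen=True)
class WindowConfig:
    """Adaptive-window parameters.

    L0 is the default (decision-segment) length, at least 10 by construction
    of the method.  Lmax defaults to 10% of the total series length when
    resolved against a panel; it may also be given explicitly.
    """

    L0: int = 10
    Lmin: int = 10
    Lmax: int | None = None
    max_length_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.L0 < 10:
            raise ConfigError(f"default window length L0={self.L0} must be >= 10")
        if not (10 <= self.Lmin <= self.L0):
            raise ConfigError(
                f"need 10 <= Lmin <= L0, got Lmin={self.Lmin}, L0={self.L0}"
            )
        if self.Lmax is not None and self.Lmax < self.L0:
            raise ConfigError(f"Lmax={self.Lmax} must be >= L0={self.L0}")
        if not (0.0 < self.max_length_fraction <= 1.0):
            raise ConfigError("max_length_fraction must lie in (0, 1]")

    def resolved(self, n_total: int) -> "WindowConfig":
        """Concrete config for a series of length ``n_total``.

        When Lmax is unset it becomes floor(max_length_fraction * n_total),
        floored at L0 so short series remain analysable.
        """
        if self.Lmax is not None:
            return self
        lmax = max(self.L0, int(math.floor(self.max_length_fraction * n_total)))
        return WindowConfig(self.L0, self.Lmin, lmax, self.max_length_fraction)


@dataclass(frozen=True)
class WindowDecision:
    """Full audit record of one adaptive-window computation."""

    segment: np.ndarray
    m: float
    z: np.ndarray
    p: np.ndarray
    H: float
    H0: float
    s: float
    smin: float
    smax: float
    L: int
    L0: int
    degenerate: bool


def fluctuation_scalars(segment: np.ndarray) -> np.ndarray:
    """Mean-normalised absolute first differences |d_{i+1} - d_i| / m.

    Normalising by the segment mean makes the scalar unit-free, so windows
    adapt identically for ug/m3 pollutant loads and dimensionless indexes.
    The magnitude |m| is used so the scalars stay nonnegative for signed
    inputs (concentrations are positive, but anomaly/normalised series need
    not be).  If the mean is exactly zero the raw absolute differences are
    returned (ordering of fluctuations is preserved; no division blow-up).
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1 or segment.size < 2:
        raise LengthError("segment must be 1-D with at least 2 values")
    if np.isnan(segment).any():
        raise DataError("segment contains missing values; caller resolves gaps")
    m = float(segment.mean())
    dif = np.abs(np.diff(segment))
    return dif if m == 0.0 else dif / abs(m)


def fluctuation_probabilities(z: np.ndarray) -> tuple[np.ndarray, bool]:
    """Normalise fluctuation scalars to a probability distribution.

    Returns ``(p, degenerate)``: if all scalars are zero (a constant
    segment) the distribution is undefined and the uniform distribution is
    returned with the degenerate flag set.
    """
    z = np.asarray(z, dtype=float)
    if (z < 0).any():
        raise DomainError("fluctuation scalars must be nonnegative")
    total = z.sum()
    if total == 0.0:
        return np.full(z.size, 1.0 / z.size), True
    return z / total, False


def fluctuation_entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits with the 0*log2(0) := 0 convention."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise DomainError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise DomainError(f"probabilities sum to {p.sum()!r}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _round_half_up(x: float) -> int:
    # window lengths are counts; ties round away from shrinking to L-1
    return int(math.floor(x + 0.5))


def adapt_window_length(segment: np.ndarray, config: WindowConfig) -> WindowDecision:
    """Decide the sliding-window length from the trailing segment.

    The segment must have exactly ``config.L0`` values and no gaps; the
    caller (the dynamic engine) is responsible for gap handling.  Requires a
    resolved config (explicit Lmax).  A constant segment is treated as
    maximal smoothness and yields L = Lmax.
    """
    if config.Lmax is None:
        raise ConfigError("config must be resolved (explicit Lmax) before use")
    segment = np.asarray(segment, dtype=float)
    if segment.size != config.L0:
        raise LengthError(
            f"segment length {segment.size} != configured L0 {config.L0}"
        )
    L0 = config.L0
    m = float(segment.mean()) if not np.isnan(segment).any() else math.nan
    z = fluctuation_scalars(segment)
    p, degenerate = fluctuation_probabilities(z)
    H = fluctuation_entropy(p)
    H0 = math.log2(L0)
    s = H / H0
    smin = float(p.min())
    smax = float(p.max())

    if degenerate:
        L = config.Lmax
    elif smin < s < smax:
        L = L0
    elif s >= smax:
        L = _round_half_up(L0 / s)
    else:  # s <= smin: concentrated fluctuation, shorten
        L = _round_half_up(s * L0)
    L = min(max(L, config.Lmin), config.Lmax)

    return WindowDecision(
        segment=segment,
        m=m,
        z=z,
        p=p,
        H=H,
        H0=H0,
        s=s,
        smin=smin,
        smax=smax,
        L=L,
        L0=L0,
        degenerate=degenerate,
    )
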