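"""Evaluation instruments for dynamic-correlation output.

Three tools quantify how a method's correlation-degree series behaves:

* :func:`fluctuation_entropy_of_series` — the same fluctuation-entropy
  pipeline used for window adaptation, applied to a whole degree series and
  normalised to [0, 1].  High scores mean the point-to-point changes are
  spread evenly through time (the series is persistently dynamic); low
  scores mean the change is concentrated in a few jumps (mostly static).
* :func:`deviation_from_static` — per-time difference between a dynamic
  degree series and the whole-period static degree of the same pair, with
  mean and max-absolute summaries.
* :func:`ranking_at_time` — the per-time ordering of associated series by
  degree, the basis for "most relevant factor right now" decisions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import LengthError, ShapeError
from .panel import CorrelationRecord
from .window import fluctuation_entropy, fluctuation_probabilities, fluctuation_scalars

__all__ = [
    "FluctuationScore",
    "DeviationSummary",
    "fluctuation_entropy_of_series",
    "deviation_from_static",
    "ranking_at_time",
]


@dataclass(frozen=True)
class FluctuationScore:
    """Normalised fluctuation entropy of one method's degree series."""

    method: str | None
    entropy: float  # in [0, 1]
    n_points: int
    degenerate: bool = False


def fluctuation_entropy_of_series(
    degrees: Sequence[float] | np.ndarray, method: str | None = None
) -> FluctuationScore:
    """Normalised fluctuation entropy of a correlation-degree series.

    The series' mean-normalised absolute changes are converted to a
    probability distribution whose Shannon entropy is divided by its maximum
    log2(len - 1).  A constant series has no change distribution at all; by
    convention it scores 1 (the maximally even limit), with the degenerate
    flag set.
    """
    degrees = np.asarray(degrees, dtype=float)
    if degrees.size < 3:
        raise LengthError("need at least 3 degrees to score fluctuation")
    if np.isnan(degrees).any():
        raise LengthError("degree series contains missing values")
    z = fluctuation_scalars(degrees)
    p, degenerate = fluctuation_probabilities(z)
    if degenerate:
        return FluctuationScore(method, 1.0, degrees.size, True)
    h = fluctuation_entropy(p) / np.log2(degrees.size - 1)
    return FluctuationScore(method, float(h), degrees.size, False)


@dataclass(frozen=True)
class DeviationSummary:
    """Per-time deviation of a dynamic method from the static degree."""

    series: pd.Series  # indexed by time: degree(t) - static
    static: float
    mean: float
    max_abs: float


def deviation_from_static(
    records: Sequence[CorrelationRecord], static: float
) -> DeviationSummary:
    """Dynamic-minus-static deviation series for one method and pair."""
    if not records:
        raise ShapeError("no records supplied")
    methods = {r.method for r in records}
    pairs = {(r.object, r.associated) for r in records}
    if len(methods) > 1 or len(pairs) > 1:
        raise ShapeError(
            f"records mix methods {methods} / pairs {pairs}; supply one of each"
        )
    dev = pd.Series(
        [r.degree - static for r in records],
        index=pd.DatetimeIndex([r.time for r in records]),
        name="deviation",
    )
    return DeviationSummary(
        series=dev,
        static=float(static),
        mean=float(dev.mean()),
        max_abs=float(dev.abs().max()),
    )


def ranking_at_time(
    records: Sequence[CorrelationRecord], t: pd.Timestamp | str
) -> list[tuple[tuple[str, str], float]]:
    """Associated series at time ``t`` ordered by degree, strongest first.

    Ties are broken lexicographically by (station, variable) id so rankings
    are deterministic.
    """
    t = pd.Timestamp(t)
    at_t = [r for r in records if r.time == t]
    if not at_t:
        import logging

        logging.getLogger("dynagra").warning("no records at %s; empty ranking", t)
        return []
    return [
        (r.associated, r.degree)
        for r in sorted(at_t, key=lambda r: (-r.degree, r.associated))
    ]
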