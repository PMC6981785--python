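"""Contrast (baseline) methods for the dynamic analysis.

Three baselines bracket the adaptive-window grey relational method
(ASW-GRA):

* ``static`` — one whole-period grey relational degree per pair, the
  traditional single-number answer.  GRA rather than Pearson is used so the
  baseline lives on the same (0, 1] degree scale as the dynamic methods
  (a Pearson variant is available via ``estimator="pearson"``).
* ``fsw_gra`` — grey relational analysis on a fixed-length sliding window;
  identical to the dynamic engine with adaptation disabled.
* ``asw_pc`` — Pearson partial correlation on the adaptive window,
  controlling for a set of covariate series; replaces the GRA half of the
  method while keeping the entropy-adaptive window.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .config import RunConfig
from .engine import Key, _window_rows, decide_window_at
from .errors import DegeneracyError, ShapeError
from .gra import pairwise_degree
from .panel import CorrelationRecord, MonitoringPanel

logger = logging.getLogger("dynagra")

__all__ = [
    "static_degree",
    "fixed_window_series",
    "partial_correlation",
    "adaptive_partial_series",
]


def static_degree(
    a: np.ndarray,
    b: np.ndarray,
    rho: float = 0.5,
    normalization: str = "minmax",
    estimator: str = "gra",
) -> float:
    """Whole-period correlation degree of two equal-length series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ShapeError(f"sequence lengths differ: {a.shape} vs {b.shape}")
    if estimator == "pearson":
        return float(np.corrcoef(a, b)[0, 1])
    return pairwise_degree(a, b, rho, normalization)


def fixed_window_series(
    panel: MonitoringPanel,
    object_key: Key,
    associated_key: Key,
    L_fixed: int | None = None,
    config: RunConfig | None = None,
) -> list[CorrelationRecord]:
    """Rolling pairwise GRA with a fixed trailing window of ``L_fixed`` hours.

    A record is emitted at every time point with at least ``L_fixed`` values
    of history including the current one; when ``L_fixed`` equals the series
    length this reduces to a single static degree at the final hour.
    """
    config = config or RunConfig()
    L_fixed = L_fixed or config.fixed_window
    if L_fixed < 2:
        raise ShapeError("fixed window must cover at least 2 points")
    arrays = [panel.array(*object_key), panel.array(*associated_key)]
    times = panel.timestamps
    records: list[CorrelationRecord] = []
    if panel.n_hours < L_fixed:
        logger.warning(
            "series length %d shorter than fixed window %d; no records",
            panel.n_hours, L_fixed,
        )
        return records
    for i in range(L_fixed - 1, panel.n_hours):
        rows = _window_rows(arrays, i, L_fixed, config.max_gap_fraction)
        if rows is None:
            logger.warning("gap budget exceeded at %s; step skipped", times[i])
            continue
        records.append(
            CorrelationRecord(
                time=times[i],
                object_station=object_key[0],
                object_variable=object_key[1],
                associated_station=associated_key[0],
                associated_variable=associated_key[1],
                method="fsw_gra",
                window_length=L_fixed,
                degree=pairwise_degree(rows[0], rows[1], config.rho, config.normalization),
            )
        )
    return records


def partial_correlation(
    y: np.ndarray, x: np.ndarray, controls: Sequence[np.ndarray] = ()
) -> float:
    """Pearson partial correlation of y and x given the control series.

    Computed by inverting the joint correlation matrix R of
    (y, x, controls...): r = -P_01 / sqrt(P_00 * P_11) with P = R^-1.  With
    no controls this is the plain Pearson correlation.
    """
    series = [np.asarray(y, dtype=float), np.asarray(x, dtype=float)] + [
        np.asarray(c, dtype=float) for c in controls
    ]
    L = series[0].size
    if any(s.size != L for s in series):
        raise ShapeError("all series must share one length")
    if L < len(controls) + 3:
        raise ShapeError(
            f"need length >= controls+3 = {len(controls) + 3}, got {L}"
        )
    names = ["y", "x"] + [f"control[{i}]" for i in range(len(controls))]
    stds = [s.std() for s in series]
    for name, sd in zip(names, stds):
        if sd == 0.0:
            raise DegeneracyError(f"series {name} is constant within the window")
    R = np.corrcoef(np.vstack(series))
    if len(series) == 2:
        return float(R[0, 1])
    # collinearity among the controls themselves is unrecoverable
    if len(controls) > 1:
        Rc = R[2:, 2:]
        if np.linalg.cond(Rc) > 1e10:
            off = np.abs(Rc - np.eye(len(controls)))
            p, q = np.unravel_index(np.argmax(off), off.shape)
            raise DegeneracyError(
                f"controls {names[2 + p]} and {names[2 + q]} are collinear "
                f"(|r| = {off[p, q]:.6f})"
            )
    if np.linalg.cond(R) < 1e10:
        P = np.linalg.inv(R)
        return float(-P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))
    # joint matrix singular because y or x is exactly explained by x/controls
    # (e.g. a control equal to y + x): the residual definition still applies
    Z = np.column_stack([np.ones(L)] + [c - c.mean() for c in series[2:]])
    resid = []
    for s in series[:2]:
        coef, *_ = np.linalg.lstsq(Z, s, rcond=None)
        resid.append(s - Z @ coef)
    sd0, sd1 = resid[0].std(), resid[1].std()
    if sd0 < 1e-12 * stds[0] or sd1 < 1e-12 * stds[1]:
        bad = names[0] if sd0 <= sd1 else names[1]
        raise DegeneracyError(
            f"series {bad} is fully explained by the controls; "
            "partial correlation undefined"
        )
    return float(np.corrcoef(resid[0], resid[1])[0, 1])


def adaptive_partial_series(
    panel: MonitoringPanel,
    object_key: Key,
    associated_key: Key,
    controls: Sequence[Key] = (),
    config: RunConfig | None = None,
) -> list[CorrelationRecord]:
    """Partial correlation on the entropy-adaptive window (ASW-PC).

    The window length is decided from the object series exactly as in the
    dynamic GRA engine; time steps whose window is too short for the control
    set (fewer than controls+3 points) are skipped with a logged warning.
    """
    config = config or RunConfig()
    obj = panel.array(*object_key)
    assoc = panel.array(*associated_key)
    ctrl = [panel.array(*k) for k in controls]
    wconfig = config.window.resolved(panel.n_hours)
    times = panel.timestamps
    records: list[CorrelationRecord] = []
    for i in range(wconfig.L0, panel.n_hours):
        L = decide_window_at(obj, i, wconfig)
        if L is None:
            continue
        L = min(L, i + 1)  # early steps: only i+1 hours of history exist
        rows = _window_rows([obj, assoc, *ctrl], i, L, config.max_gap_fraction)
        if rows is None:
            logger.warning("gap budget exceeded at %s; step skipped", times[i])
            continue
        if rows[0].size < len(controls) + 3:
            logger.warning(
                "window at %s too short for %d controls; step skipped",
                times[i], len(controls),
            )
            continue
        try:
            degree = partial_correlation(rows[0], rows[1], rows[2:])
        except DegeneracyError as exc:
            logger.warning("degenerate window at %s: %s; step skipped", times[i], exc)
            continue
        records.append(
            CorrelationRecord(
                time=times[i],
                object_station=object_key[0],
                object_variable=object_key[1],
                associated_station=associated_key[0],
                associated_variable=associated_key[1],
                method="asw_pc",
                window_length=L,
                degree=float(np.clip(degree, -1.0, 1.0)),
            )
        )
    return records
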