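"""Grey relational analysis (GRA).

GRA scores how closely each comparison sequence x_k tracks a reference
sequence y by the geometric similarity of their (normalised) curves.  With
Delta_k(i) = |y(i) - x_k(i)| and the two-level extrema

    Dmin = min_k min_i Delta_k(i),   Dmax = max_k max_i Delta_k(i),

the relational coefficient at each point is

    xi_k(i) = (Dmin + rho * Dmax) / (Delta_k(i) + rho * Dmax),

with resolution ratio rho in (0, 1) (conventionally 0.5), and the
correlation degree is the mean r_k = mean_i xi_k(i), which lies in (0, 1].
Note the extrema are global over ALL comparison sequences: with several
comparisons the coefficients of one sequence depend on the whole set.  The
pairwise helper exists precisely so station-station matrices are
set-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError, DomainError, ShapeError

__all__ = [
    "GRAInstance",
    "RelationalResult",
    "normalize_sequences",
    "relational_coefficients",
    "relational_degree",
    "grey_relational_degrees",
    "pairwise_degree",
]

NORMALIZATIONS = ("minmax", "initial_value", "none")


@dataclass(frozen=True)
class GRAInstance:
    """Reference sequence y(i) plus n comparison sequences x_k(i).

    ``comparisons`` has shape (n, L); all sequences share length L >= 2.
    """

    reference: np.ndarray
    comparisons: np.ndarray
    rho: float = 0.5

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float)
        cmp_ = np.atleast_2d(np.asarray(self.comparisons, dtype=float))
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "comparisons", cmp_)
        if ref.ndim != 1 or ref.size < 2:
            raise ShapeError("reference must be 1-D with length >= 2")
        if cmp_.shape[0] < 1 or cmp_.shape[1] != ref.size:
            raise ShapeError(
                f"comparisons shape {cmp_.shape} incompatible with reference "
                f"length {ref.size}"
            )
        if not (0.0 < self.rho < 1.0):
            raise DomainError(f"resolution ratio rho={self.rho} must satisfy 0 < rho < 1")

    @property
    def n(self) -> int:
        return self.comparisons.shape[0]

    @property
    def L(self) -> int:
        return self.reference.size


@dataclass(frozen=True)
class RelationalResult:
    """Coefficient matrix xi_k(i) (n x L) with the two-level extrema."""

    xi: np.ndarray
    delta_min: float
    delta_max: float

    @property
    def degrees(self) -> np.ndarray:
        return relational_degree(self)


def _minmax(seq: np.ndarray) -> np.ndarray:
    lo, hi = seq.min(), seq.max()
    if hi == lo:
        # constant sequence: 0/0 scaling is undefined; keep it mid-range
        return np.full_like(seq, 0.5)
    return (seq - lo) / (hi - lo)


def normalize_sequences(instance: GRAInstance, method: str = "minmax") -> GRAInstance:
    """Remove measurement-unit effects before comparing curves.

    ``minmax`` (default) scales each sequence independently onto [0, 1];
    ``initial_value`` divides by the first value; ``none`` passes through.
    Min-max is idempotent on non-constant sequences.
    """
    if method not in NORMALIZATIONS:
        raise ConfigError(f"unknown normalization {method!r}; expected {NORMALIZATIONS}")
    if method == "none":
        return instance
    if method == "minmax":
        ref = _minmax(instance.reference)
        cmp_ = np.apply_along_axis(_minmax, 1, instance.comparisons)
        return replace(instance, reference=ref, comparisons=cmp_)
    # initial_value
    if instance.reference[0] == 0 or (instance.comparisons[:, 0] == 0).any():
        raise DomainError("initial_value normalization undefined for a zero first value")
    ref = instance.reference / instance.reference[0]
    cmp_ = instance.comparisons / instance.comparisons[:, :1]
    return replace(instance, reference=ref, comparisons=cmp_)


def relational_coefficients(
    instance: GRAInstance, normalized: bool = False, normalization: str = "minmax"
) -> RelationalResult:
    """Compute the coefficient matrix xi_k(i).

    Unless ``normalized`` says the caller already did so, sequences are
    normalised first.  If every comparison is identical to the reference
    (Dmax == 0) the coefficients are all 1, the natural limit.
    """
    if not normalized:
        instance = normalize_sequences(instance, normalization)
    delta = np.abs(instance.reference[None, :] - instance.comparisons)
    dmin = float(delta.min())
    dmax = float(delta.max())
    if dmax == 0.0:
        xi = np.ones_like(delta)
    else:
        xi = (dmin + instance.rho * dmax) / (delta + instance.rho * dmax)
    return RelationalResult(xi=xi, delta_min=dmin, delta_max=dmax)


def relational_degree(result: RelationalResult) -> np.ndarray:
    """Correlation degrees r_k = mean_i xi_k(i), one per comparison."""
    return result.xi.mean(axis=1)


def grey_relational_degrees(
    reference: np.ndarray,
    comparisons: np.ndarray,
    rho: float = 0.5,
    normalization: str = "minmax",
) -> np.ndarray:
    """Degrees of all comparisons against the reference (joint extrema)."""
    inst = GRAInstance(reference=reference, comparisons=comparisons, rho=rho)
    return relational_coefficients(inst, normalization=normalization).degrees


def pairwise_degree(
    a: np.ndarray, b: np.ndarray, rho: float = 0.5, normalization: str = "minmax"
) -> float:
    """Single-pair GRA degree; symmetric because normalisation is per-sequence
    and |a - b| does not depend on which one is the reference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ShapeError(f"sequence lengths differ: {a.shape} vs {b.shape}")
    return float(grey_relational_degrees(a, b[None, :], rho, normalization)[0])
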