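"""Cubic B-spline basis for trait-value-dependent influence functions.

The influence of a phenological trait (e.g. days to heading) on a second
trait (e.g. culm length) is modelled as a smooth function

    L(y) = sum_m P_m * phi_m(y),

where the ``phi_m`` are cubic (order-4) B-spline basis functions on a knot
vector with full-multiplicity boundary knots, and the ``P_m`` are weights
with units of (influenced-trait unit)/(phenological-trait unit), e.g.
cm/day.  With eight basis functions the knot vector has twelve knots: four
coincident at each boundary plus four equally spaced interior knots.

Knot placement follows a midpoint rule: the observed minimum of the
(centered) phenological trait sits halfway between the lower boundary knot
and the first interior knot, and the maximum halfway between the last
interior knot and the upper boundary knot, with all inter-knot intervals
equal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "KnotVector",
    "SplineWeights",
    "build_knots",
    "basis_matrix",
    "de_boor_matrix",
    "basis_eval",
    "influence_eval",
    "save_knots",
    "load_knots",
]


@dataclass(frozen=True)
class KnotVector:
    """Non-decreasing knot sequence with full-multiplicity boundaries.

    ``n_basis = len(knots) - order`` cubic basis functions are defined on
    the sequence.  The default model uses 12 knots / 8 basis functions.
    """

    knots: tuple[float, ...]
    order: int = 4

    def __post_init__(self) -> None:
        t = np.asarray(self.knots, dtype=float)
        if self.order != 4:
            raise ValueError("only cubic (order-4) splines are supported")
        if t.size < 2 * self.order + 1:
            raise ValueError(
                f"need at least {2 * self.order + 1} knots, got {t.size}"
            )
        if not np.all(np.isfinite(t)):
            raise ValueError("knots must be finite")
        if np.any(np.diff(t) < 0):
            raise ValueError("knots must be non-decreasing")
        k = self.order
        if not (np.all(t[:k] == t[0]) and np.all(t[-k:] == t[-1])):
            raise ValueError("first and last 4 knots must be coincident")
        if t[0] >= t[-1]:
            raise ValueError("degenerate knot range")
        interior = t[k:-k]
        if np.any(interior <= t[0]) or np.any(interior >= t[-1]):
            raise ValueError("interior knots must lie strictly inside the boundaries")
        object.__setattr__(self, "knots", tuple(float(x) for x in t))

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.order

    @property
    def lower(self) -> float:
        """Lower boundary knot t_L."""
        return self.knots[0]

    @property
    def upper(self) -> float:
        """Upper boundary knot t_U."""
        return self.knots[-1]

    @property
    def y_min(self) -> float:
        """Trait value midway between the lower boundary and first interior knot."""
        k = self.order
        return 0.5 * (self.knots[k - 1] + self.knots[k])

    @property
    def y_max(self) -> float:
        """Trait value midway between the last interior knot and the upper boundary."""
        k = self.order
        return 0.5 * (self.knots[-k - 1] + self.knots[-k])

    def support(self, m: int) -> tuple[float, float]:
        """Support interval (knots[m], knots[m+order]) of basis ``m``."""
        return self.knots[m], self.knots[m + self.order]


@dataclass
class SplineWeights:
    """Weights of the basis expansion plus their smoothness variance.

    ``P`` has one entry per basis function; ``sigma_P2`` is the variance of
    the second-difference random walk that penalises curvature of L.
    """

    P: np.ndarray
    sigma_P2: float = 1.0

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float).ravel()
        if self.sigma_P2 <= 0:
            raise ValueError("sigma_P2 must be positive")


def build_knots(y_min: float, y_max: float, n_basis: int = 8) -> KnotVector:
    """Build the knot vector from the observed trait range.

    The ``q = n_basis - 4`` interior knots are equally spaced with interval
    ``delta = (y_max - y_min) / q``; the boundary knots sit half an interval
    outside the data range so that ``y_min`` and ``y_max`` are the midpoints
    of the first and last non-empty inter-knot intervals.
    """
    if not (np.isfinite(y_min) and np.isfinite(y_max)):
        raise ValueError("y_min and y_max must be finite")
    if y_min >= y_max:
        raise ValueError(f"invalid range: y_min={y_min!r} must be < y_max={y_max!r}")
    if n_basis < 5:
        raise ValueError("need at least 5 basis functions (1 interior knot)")
    q = n_basis - 4
    delta = (y_max - y_min) / q
    t_lo = y_min - delta / 2.0
    t_hi = y_max + delta / 2.0
    interior = [t_lo + j * delta for j in range(1, q + 1)]
    knots = [t_lo] * 4 + interior + [t_hi] * 4
    return KnotVector(tuple(knots))


def basis_matrix(kv: KnotVector, y) -> np.ndarray:
    """Evaluate all basis functions at ``y`` (Cox–de Boor recursion).

    Returns an array of shape ``(len(y), n_basis)``.  Points outside the
    knot range get all-zero rows; the upper boundary is mapped into the
    last non-empty interval so the basis sums to one there.
    """
    return de_boor_matrix(np.asarray(kv.knots), kv.order, y)


def de_boor_matrix(t: np.ndarray, k: int, y) -> np.ndarray:
    """Cox–de Boor recursion on an arbitrary non-decreasing knot sequence.

    Defines ``len(t) - k`` order-``k`` basis functions; convention 0/0 = 0
    and the last knot belongs to the last non-empty interval.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    t = np.asarray(t, dtype=float)
    n_int = t.size - 1
    # order-1 (degree-0) indicators on half-open intervals [t_j, t_{j+1})
    B = np.zeros((y.size, n_int))
    for j in range(n_int):
        if t[j] < t[j + 1]:
            B[:, j] = (y >= t[j]) & (y < t[j + 1])
    # upper boundary belongs to the last non-empty interval
    nonempty = np.nonzero(t[:-1] < t[1:])[0]
    B[y == t[-1], nonempty[-1]] = 1.0
    for d in range(1, k):
        nb = n_int - d
        Bn = np.zeros((y.size, nb))
        for j in range(nb):
            den1 = t[j + d] - t[j]
            den2 = t[j + d + 1] - t[j + 1]
            acc = np.zeros(y.size)
            if den1 > 0:
                acc += (y - t[j]) / den1 * B[:, j]
            if den2 > 0:
                acc += (t[j + d + 1] - y) / den2 * B[:, j + 1]
            Bn[:, j] = acc
        B = Bn
    return B


def basis_eval(kv: KnotVector, m: int, y: float) -> float:
    """Value of basis function ``m`` at ``y`` (0 outside its support)."""
    if not 0 <= m < kv.n_basis:
        raise ValueError(f"basis index {m} outside 0..{kv.n_basis - 1}")
    return float(basis_matrix(kv, [y])[0, m])


def influence_eval(kv: KnotVector, w: SplineWeights, y) -> np.ndarray | float:
    """Evaluate the influence function L(y) = sum_m P_m phi_m(y).

    Raises if any point lies outside the knot range: the model never
    evaluates L there and the spline is undefined beyond the boundaries.
    """
    if w.P.size != kv.n_basis:
        raise ValueError(f"expected {kv.n_basis} weights, got {w.P.size}")
    arr = np.atleast_1d(np.asarray(y, dtype=float))
    if np.any(arr < kv.lower) or np.any(arr > kv.upper):
        raise ValueError(
            f"evaluation point outside knot range [{kv.lower}, {kv.upper}]"
        )
    vals = basis_matrix(kv, arr) @ w.P
    return float(vals[0]) if np.isscalar(y) or np.ndim(y) == 0 else vals


def save_knots(kv: KnotVector, path) -> None:
    """Write the knot sequence as a single-column text file."""
    Path(path).write_text("\n".join(repr(x) for x in kv.knots) + "\n")


def load_knots(path) -> KnotVector:
    """Read a knot sequence written by :func:`save_knots`."""
    vals = [float(line) for line in Path(path).read_text().split()]
    return KnotVector(tuple(vals))
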