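"""Normalized bivariate rational surfaces coupling granule attributes to
tableting model parameters.

A raw process variable x in [lb, ub) is mapped to X = ((x-lb)/(ub-x))^r in
[0, +inf), and each tableting-model parameter xi is expressed as a rational
surface

    f(X, Y) = (p1*X*Y + p2*X + p3*Y + p4) / (q1*X*Y + q2*X + q3*Y + 1).

Nine constrained variants of f (progressively zeroing coefficients and/or
fixing the exponents at 1) form a model library of 25 variant pairs, one
surface per model parameter; the corner and edge limits of f have direct
physical readings (f(0,0) = p4, f(inf,inf) = p1/q1, ...).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NormalizedVariable",
    "RationalSurface",
    "ModelPair",
    "VariantSpec",
    "SingularSurfaceError",
    "BelowLowerBoundError",
    "NormalizationOverflowError",
    "COEFF_NAMES",
    "normalize",
    "variant_mask",
    "eval_surface",
    "limit_profile",
    "enumerate_library",
    "count_parameters",
]

COEFF_NAMES = ("p1", "p2", "p3", "p4", "q1", "q2", "q3")

#: coefficient names forced to zero, and whether rX = rY = 1, per variant
_VARIANT_TABLE: dict[int, tuple[frozenset, bool]] = {
    1: (frozenset(), False),
    2: (frozenset(), True),
    3: (frozenset({"p3", "q3"}), False),
    4: (frozenset({"p3", "q3"}), True),
    5: (frozenset({"p2", "q2"}), False),
    6: (frozenset({"p2", "q2"}), True),
    7: (frozenset({"p2", "p3", "q2", "q3"}), False),
    8: (frozenset({"p2", "p3", "q2", "q3"}), True),
    9: (frozenset({"p1", "p2", "p3", "q1", "q2", "q3"}), True),
}


class SingularSurfaceError(ZeroDivisionError):
    """The rational surface is singular (zero or indeterminate denominator)
    at the requested point."""


class BelowLowerBoundError(ValueError):
    """Raw value below the lower bound of its normalization interval."""


class NormalizationOverflowError(ValueError):
    """Raw value at or above the upper bound: the normalized value is not
    finite.  Distinct from :class:`BelowLowerBoundError`."""


@dataclass(frozen=True)
class NormalizedVariable:
    """Normalization interval [lb, ub) and exponent r for one raw variable."""

    lb: float
    ub: float
    r: float = 1.0

    def __post_init__(self) -> None:
        if not self.lb < self.ub:
            raise ValueError(f"need lb < ub, got [{self.lb}, {self.ub}]")
        if not 0.0 < self.r <= 10.0:
            raise ValueError(f"exponent must lie in (0, 10], got {self.r}")


def normalize(x: float, v: NormalizedVariable) -> float:
    """Map raw x in [lb, ub) to X = ((x - lb)/(ub - x))^r in [0, +inf)."""
    if x < v.lb:
        raise BelowLowerBoundError(f"x={x} below lower bound {v.lb}")
    if x >= v.ub:
        raise NormalizationOverflowError(
            f"x={x} at or above upper bound {v.ub}; the mapped value is "
            "infinite (evaluate surfaces at the limit instead)")
    return ((x - v.lb) / (v.ub - x)) ** v.r


@dataclass(frozen=True)
class VariantSpec:
    """Constraint set for one library variant: which coefficients are zeroed
    and whether the exponents are fixed at 1."""

    id: int
    zeroed: frozenset
    exponents_fixed: bool

    @property
    def free_coeffs(self) -> tuple[str, ...]:
        return tuple(c for c in COEFF_NAMES if c not in self.zeroed)

    @property
    def n_free_coeffs(self) -> int:
        """Free coefficients, excluding the exponents."""
        return len(COEFF_NAMES) - len(self.zeroed)

    @property
    def n_parameters(self) -> int:
        """Parameter count as tabulated: coefficients plus exponents where
        the exponents are free."""
        return self.n_free_coeffs + (0 if self.exponents_fixed else 2)


def variant_mask(id: int) -> VariantSpec:
    """Constraint set of library variant ``id`` (1 = fully free bivariate
    rational surface ... 9 = constant p4)."""
    try:
        zeroed, fixed = _VARIANT_TABLE[id]
    except KeyError:
        raise ValueError(f"variant id must be in 1..9, got {id}") from None
    return VariantSpec(id=id, zeroed=zeroed, exponents_fixed=fixed)


@dataclass(frozen=True)
class RationalSurface:
    """One constrained rational surface: a library variant with numerical
    coefficients.  Coefficients zeroed by the variant mask must be 0."""

    variant: int
    p1: float = 0.0
    p2: float = 0.0
    p3: float = 0.0
    p4: float = 0.0
    q1: float = 0.0
    q2: float = 0.0
    q3: float = 0.0

    def __post_init__(self) -> None:
        spec = variant_mask(self.variant)
        for name in spec.zeroed:
            if getattr(self, name) != 0.0:
                raise ValueError(
                    f"variant {self.variant} zeroes coefficient {name}, "
                    f"got {getattr(self, name)}")

    @property
    def spec(self) -> VariantSpec:
        return variant_mask(self.variant)

    def coeffs(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in COEFF_NAMES}

    def to_dict(self) -> dict:
        d = {"variant": self.variant}
        d.update({c: getattr(self, c) for c in self.spec.free_coeffs})
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RationalSurface":
        return cls(**d)


def _ratio(num: float, den: float, where: str) -> float:
    if den == 0.0:
        raise SingularSurfaceError(
            f"singular surface at {where}: numerator {num}, denominator 0")
    return num / den


def _eval_scalar(s: RationalSurface, X: float, Y: float) -> float:
    """Evaluate f(X, Y) honoring limit algebra at infinite arguments."""
    xinf, yinf = math.isinf(X), math.isinf(Y)
    if not xinf and not yinf:
        num = s.p1 * X * Y + s.p2 * X + s.p3 * Y + s.p4
        den = s.q1 * X * Y + s.q2 * X + s.q3 * Y + 1.0
        return _ratio(num, den, f"(X={X}, Y={Y})")
    if xinf and yinf:
        if s.q1 != 0.0:
            return s.p1 / s.q1
        if s.p1 != 0.0:
            raise SingularSurfaceError("f(+inf,+inf) diverges: p1 != 0, q1 = 0")
        # X*Y terms absent: the limit is set by the surviving linear terms
        if s.p2 == s.q2 == 0.0:  # no X dependence left
            if s.q3 != 0.0:
                return s.p3 / s.q3
            if s.p3 != 0.0:
                raise SingularSurfaceError("f(+inf,+inf) diverges along Y")
            return s.p4
        if s.p3 == s.q3 == 0.0:  # no Y dependence left
            if s.q2 != 0.0:
                return s.p2 / s.q2
            if s.p2 != 0.0:
                raise SingularSurfaceError("f(+inf,+inf) diverges along X")
            return s.p4
        raise SingularSurfaceError(
            "f(+inf,+inf) is path dependent for this coefficient set")
    if xinf:
        num1, den1 = s.p1 * Y + s.p2, s.q1 * Y + s.q2
        if den1 != 0.0:
            return num1 / den1
        if num1 != 0.0:
            raise SingularSurfaceError(f"f(+inf, Y={Y}) diverges")
        # X enters neither numerator nor denominator at this Y
        return _ratio(s.p3 * Y + s.p4, s.q3 * Y + 1.0, f"(+inf, Y={Y})")
    # Y infinite, X finite
    num1, den1 = s.p1 * X + s.p3, s.q1 * X + s.q3
    if den1 != 0.0:
        return num1 / den1
    if num1 != 0.0:
        raise SingularSurfaceError(f"f(X={X}, +inf) diverges")
    return _ratio(s.p2 * X + s.p4, s.q2 * X + 1.0, f"(X={X}, +inf)")


def eval_surface(s: RationalSurface, X, Y):
    """Evaluate the surface at (X, Y); arguments may be scalars or arrays and
    may be ``+inf`` (the appropriate algebraic limit is returned)."""
    Xa = np.asarray(X, dtype=float)
    Ya = np.asarray(Y, dtype=float)
    if Xa.ndim == 0 and Ya.ndim == 0:
        return _eval_scalar(s, float(Xa), float(Ya))
    Xb, Yb = np.broadcast_arrays(Xa, Ya)
    if np.all(np.isfinite(Xb)) and np.all(np.isfinite(Yb)):
        num = s.p1 * Xb * Yb + s.p2 * Xb + s.p3 * Yb + s.p4
        den = s.q1 * Xb * Yb + s.q2 * Xb + s.q3 * Yb + 1.0
        if np.any(den == 0.0):
            raise SingularSurfaceError("singular surface on the input grid")
        return num / den
    out = np.empty(Xb.shape, dtype=float)
    for idx in np.ndindex(Xb.shape):
        out[idx] = _eval_scalar(s, float(Xb[idx]), float(Yb[idx]))
    return out


def limit_profile(s: RationalSurface, edge: str):
    """Univariate boundary profile of the surface along one edge.

    ``edge`` is one of ``"X=0"``, ``"X=inf"``, ``"Y=0"``, ``"Y=inf"``; the
    returned callable takes the remaining variable.  E.g. the ``X=0`` edge
    is (p3*Y + p4)/(q3*Y + 1) and ``X=inf`` is (p1*Y + p2)/(q1*Y + q2).
    """
    edges = {
        "X=0": lambda t: eval_surface(s, 0.0, t),
        "X=inf": lambda t: eval_surface(s, math.inf, t),
        "Y=0": lambda t: eval_surface(s, t, 0.0),
        "Y=inf": lambda t: eval_surface(s, t, math.inf),
    }
    try:
        return edges[edge]
    except KeyError:
        raise ValueError(f"edge must be one of {sorted(edges)}, got {edge!r}"
                         ) from None


@dataclass(frozen=True)
class ModelPair:
    """One library member: a variant for each of the two coupled model
    parameters, with the normalization exponents shared across both."""

    variant_xi1: int
    variant_xi2: int
    shared_exponents: bool = True

    def __post_init__(self) -> None:
        variant_mask(self.variant_xi1)
        variant_mask(self.variant_xi2)

    @property
    def exponents_fixed(self) -> bool:
        """Exponents are fixed at 1 only when both members fix them."""
        return (variant_mask(self.variant_xi1).exponents_fixed
                and variant_mask(self.variant_xi2).exponents_fixed)

    def astuple(self) -> tuple[int, int]:
        return (self.variant_xi1, self.variant_xi2)


def enumerate_library() -> list[ModelPair]:
    """The 25-pair model library: the diagonal pairs (v, v) for v = 1..8,
    the pairs (v, 9) for v = 1..8, and (9, w) for w = 1..9 — a deliberate
    subset of the 81 possible variant combinations."""
    pairs = [ModelPair(v, v) for v in range(1, 9)]
    pairs += [ModelPair(v, 9) for v in range(1, 9)]
    pairs += [ModelPair(9, w) for w in range(1, 10)]
    return pairs


def count_parameters(pair: ModelPair, n_constants: int = 0) -> int:
    """Total fitted-parameter count Np for a library pair.

    Free coefficients of both surfaces (exponents excluded), plus the two
    shared exponents when either member leaves them free, plus any scalar
    model constants fitted alongside (e.g. the Kawakita pressure parameter
    b, or the recovery exponent n).
    """
    if pair.astuple() not in {p.astuple() for p in enumerate_library()}:
        raise ValueError(f"pair {pair.astuple()} is not in the model library")
    s1 = variant_mask(pair.variant_xi1)
    s2 = variant_mask(pair.variant_xi2)
    n_exp = 0 if pair.exponents_fixed else 2
    return s1.n_free_coeffs + s2.n_free_coeffs + n_exp + n_constants
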