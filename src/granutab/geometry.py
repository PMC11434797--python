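"""Doubly convex tablet geometry, volumes, relative densities and strength.

Unit contract (used consistently across the package): lengths in mm,
volumes in mm^3, weight in mg, densities in g/cc (numerically equal to
mg/mm^3), diametral breaking force in N, punch force in kN, stress in MPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ToolGeometry",
    "PressSetpoints",
    "TabletMeasurement",
    "cap_volume",
    "fill_volume",
    "compact_volume",
    "relative_density",
    "pitt_tensile_strength",
    "pitt_breaking_force",
    "filling_efficacy",
]


@dataclass(frozen=True)
class ToolGeometry:
    """Punch/die tooling for a doubly convex tablet.

    Parameters
    ----------
    D : float
        Punch and die diameter, mm.
    h : float
        Cup depth of each convex punch face, mm.
    """

    D: float
    h: float

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"diameter must be positive, got {self.D}")
        if self.h < 0:
            raise ValueError(f"cup depth must be non-negative, got {self.h}")
        if self.h >= self.D / 2:
            raise ValueError("cup depth must be smaller than the punch radius")


@dataclass(frozen=True)
class PressSetpoints:
    """Tablet-press control variables for one tableting condition.

    t_fill is the dosing (fill-depth) position, t_pc the pre-compression
    thickness and t_in_die the main-compression thickness, all in mm.
    Turret and feed-frame speeds (rev/min) are carried as metadata.
    """

    t_fill: float
    t_pc: float
    t_in_die: float
    turret_speed: float = 25.0
    feedframe_speed: float = 40.0

    def __post_init__(self) -> None:
        if not (self.t_fill > self.t_pc >= self.t_in_die > 0):
            raise ValueError(
                "setpoints must satisfy t_fill > t_pc >= t_in_die > 0; got "
                f"({self.t_fill}, {self.t_pc}, {self.t_in_die})"
            )


@dataclass(frozen=True)
class TabletMeasurement:
    """At-line tablet measurements: weight W (mg), overall thickness
    H_tablet (mm), band thickness t_tablet (mm) and diametral breaking
    force F_hardness (N)."""

    W: float
    H_tablet: float
    t_tablet: float
    F_hardness: float

    def __post_init__(self) -> None:
        for name in ("W", "H_tablet", "t_tablet", "F_hardness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_overall_thickness(
        cls, W: float, H_tablet: float, F_hardness: float, geom: ToolGeometry
    ) -> "TabletMeasurement":
        """Build a measurement record deriving the band thickness from
        t_tablet = H_tablet - 2h."""
        return cls(W=W, H_tablet=H_tablet, t_tablet=H_tablet - 2 * geom.h,
                   F_hardness=F_hardness)


def cap_volume(geom: ToolGeometry) -> float:
    """Total volume of the two convex caps, mm^3: (pi*h/6)*(3D^2/4 + h^2)."""
    return math.pi * geom.h / 6.0 * (3.0 * geom.D**2 / 4.0 + geom.h**2)


def fill_volume(geom: ToolGeometry, t_fill) -> float:
    """Die volume at the dosing position, mm^3.

    V_fill = pi*D^2*t_fill/4 + (pi*h/12)*(3D^2/4 + h^2).  Note the cap term
    carries half the weight of the compacted-state volumes: the fill state
    exposes a single punch cup.
    """
    t_fill = np.asarray(t_fill, dtype=float)
    if np.any(t_fill <= 0):
        raise ValueError("t_fill must be positive")
    out = math.pi * geom.D**2 * t_fill / 4.0 + 0.5 * cap_volume(geom)
    return float(out) if out.ndim == 0 else out


def compact_volume(geom: ToolGeometry, t) -> float:
    """Tablet volume at band thickness t, mm^3 (serves the pre-compression,
    in-die and out-of-die states): V = pi*D^2*t/4 + (pi*h/6)*(3D^2/4 + h^2)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("thickness must be positive")
    out = math.pi * geom.D**2 * t / 4.0 + cap_volume(geom)
    return float(out) if out.ndim == 0 else out


def relative_density(W, rho_t: float, V) -> float:
    """Relative density (solid fraction) rho = W / (rho_t * V).

    W in mg, rho_t in g/cc, V in mm^3; mg/mm^3 equals g/cc numerically so
    no conversion factor appears.
    """
    W = np.asarray(W, dtype=float)
    V = np.asarray(V, dtype=float)
    if rho_t <= 0 or np.any(W <= 0) or np.any(V <= 0):
        raise ValueError("weight, true density and volume must be positive")
    out = W / (rho_t * V)
    return float(out) if out.ndim == 0 else out


def _pitt_denominator(D: float, H_tablet, t_tablet):
    return (2.84 * H_tablet / D - 0.126 * H_tablet / t_tablet
            + 3.15 * t_tablet / D + 0.01)


def pitt_tensile_strength(F, geom: ToolGeometry, H_tablet, t_tablet) -> float:
    """Tensile strength of a doubly convex tablet from the diametral
    breaking force (Pitt's relation), MPa.

    sigma_t = (10F / (pi D^2)) / (2.84 H/D - 0.126 H/t + 3.15 t/D + 0.01)
    with F in N, lengths in mm.
    """
    F = np.asarray(F, dtype=float)
    t_tablet = np.asarray(t_tablet, dtype=float)
    H_tablet = np.asarray(H_tablet, dtype=float)
    if np.any(F < 0):
        raise ValueError("breaking force must be non-negative")
    if np.any(t_tablet <= 0):
        raise ValueError("band thickness must be positive")
    denom = _pitt_denominator(geom.D, H_tablet, t_tablet)
    if np.any(denom <= 0):
        raise ValueError("geometrically invalid tablet: non-positive "
                         "Pitt denominator")
    out = (10.0 * F / (math.pi * geom.D**2)) / denom
    return float(out) if out.ndim == 0 else out


def pitt_breaking_force(sigma_t, geom: ToolGeometry, H_tablet, t_tablet):
    """Inverse of :func:`pitt_tensile_strength`: breaking force (N) that a
    tablet of the given geometry and tensile strength (MPa) would show."""
    sigma_t = np.asarray(sigma_t, dtype=float)
    denom = _pitt_denominator(geom.D, H_tablet, t_tablet)
    if np.any(denom <= 0):
        raise ValueError("geometrically invalid tablet: non-positive "
                         "Pitt denominator")
    out = sigma_t * denom * math.pi * geom.D**2 / 10.0
    return float(out) if out.ndim == 0 else out


def filling_efficacy(W, rho_b: float, V_fill) -> float:
    """Filling efficacy eta = W / (rho_b * V_fill): the ratio of the actual
    die fill to the ideal fill at the off-line bulk density rho_b (g/cc)."""
    W = np.asarray(W, dtype=float)
    V_fill = np.asarray(V_fill, dtype=float)
    if rho_b <= 0 or np.any(W <= 0) or np.any(V_fill <= 0):
        raise ValueError("weight, bulk density and fill volume must be positive")
    out = W / (rho_b * V_fill)
    return float(out) if out.ndim == 0 else out
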