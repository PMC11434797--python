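"""Tableting reduced-order models and their granule-coupled forms.

Four ROMs cover the stages of compaction: a packing-fraction model for die
filling and tablet weight, a jamming-modified Kawakita model for the main
compaction force, a power-law elastic-recovery model for unloading (giving
the out-of-die density), and Leuenberger's bonding-point model for tensile
strength.  In the coupled forms, each ROM parameter set xi is replaced by a
pair of rational surfaces of the normalized ribbon density X and either the
normalized mean granule size Y or the normalized packing fraction Z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .coupling import (NormalizedVariable, RationalSurface, SingularSurfaceError,
                       eval_surface, normalize)
from .geometry import ToolGeometry, PressSetpoints, fill_volume, compact_volume
from .gsd import GranuleBatch, mean_gsd, packing_covariates

__all__ = [
    "KawakitaParams", "RecoveryParams", "StrengthParams", "PackingParams",
    "BrouwersReference", "CoupledROM", "InfeasibleStateError",
    "NoCoherentTabletError", "compaction_force", "elastic_recovery",
    "out_of_die_density", "tensile_strength", "packing_fraction",
    "tablet_weight", "brouwers_packing", "evaluate_coupled",
    "RHO_C_RIB_DEFAULT",
]

#: critical ribbon relative density: the smallest density at which a ribbon
#: forms, shared by all coupled ROMs
RHO_C_RIB_DEFAULT = 0.566


class InfeasibleStateError(ValueError):
    """The compaction state violates a ROM feasibility condition."""


class NoCoherentTabletError(ValueError):
    """Tablet density below the smallest density forming a coherent tablet."""


@dataclass(frozen=True)
class KawakitaParams:
    """Jamming-modified Kawakita parameters: total compressibility a,
    pressure parameter b (1/MPa) and critical in-die density rho_c."""

    a: float
    b: float
    rho_c: float

    def __post_init__(self) -> None:
        if not 0.0 < self.a < 1.0:
            raise ValueError(f"a must lie in (0, 1), got {self.a}")
        if self.b <= 0:
            raise ValueError("b must be positive")
        if not 0.0 < self.rho_c < 1.0:
            raise ValueError("rho_c must lie in (0, 1)")


@dataclass(frozen=True)
class RecoveryParams:
    """Elastic-recovery parameters: recovery at zero porosity eps0, onset
    density rho_c_eps, and nonlinearity exponent n_exp."""

    eps0: float
    rho_c_eps: float
    n_exp: float

    def __post_init__(self) -> None:
        if not 0.0 < self.eps0 < 1.0:
            raise ValueError("eps0 must lie in (0, 1)")
        if not 0.0 < self.rho_c_eps < 1.0:
            raise ValueError("rho_c_eps must lie in (0, 1)")
        if self.n_exp <= 0:
            raise ValueError("n_exp must be positive")


@dataclass(frozen=True)
class StrengthParams:
    """Leuenberger strength parameters: zero-porosity strength sigma0 (MPa)
    and the smallest density forming a coherent tablet rho_c_sigma."""

    sigma0: float
    rho_c_sigma: float

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if not 0.0 < self.rho_c_sigma < 1.0:
            raise ValueError("rho_c_sigma must lie in (0, 1)")


@dataclass(frozen=True)
class PackingParams:
    """Die-filling packing-fraction surface phi = p4(q2 X + 1)/(q1 XY + q2 X + 1).

    p4 is the unimodal-limit packing fraction; q1 is the mode-interaction
    coefficient and is negative under the fitted sign convention (so that
    phi >= p4 on the unit square); q2 scales the size-ratio covariate.
    """

    p4: float
    q1: float
    q2: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p4 < 1.0:
            raise ValueError("p4 must lie in (0, 1)")

    @property
    def p2(self) -> float:
        """Numerator X coefficient implied by the unimodal constraint
        p2 = q2 * p4."""
        return self.q2 * self.p4


@dataclass(frozen=True)
class BrouwersReference:
    """Reference bimodal hard-sphere packing relation: random packing
    fraction phi_rp of the unimodal system and packing-mode constant C."""

    phi_rp: float
    C: float

    def __post_init__(self) -> None:
        if not 0.0 < self.phi_rp < 1.0:
            raise ValueError("phi_rp must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Base (uncoupled) ROMs


def kawakita_feasible(rho_in_die, a, rho_c):
    """Feasibility of the compaction state: rho - rho_c > 0 and
    rho*(a - 1) + rho_c > 0 (both required for a positive force)."""
    rho = np.asarray(rho_in_die, dtype=float)
    return (rho - rho_c > 0) & (rho * (a - 1.0) + rho_c > 0)


def compaction_force(rho_in_die, kp: KawakitaParams, geom: ToolGeometry):
    """Main compaction force, kN:

        F = pi D^2 (rho - rho_c) / (4 b (rho (a - 1) + rho_c)),

    with D in mm and b in 1/MPa the numerator is in N; the result is
    converted to kN.  At rho = rho_c (jamming onset) the force is zero.
    """
    rho = np.asarray(rho_in_die, dtype=float)
    ok = (rho - kp.rho_c >= 0) & (rho * (kp.a - 1.0) + kp.rho_c > 0)
    if not np.all(ok):
        raise InfeasibleStateError(
            "in-die density violates the Kawakita feasibility conditions")
    force_n = (math.pi * geom.D**2 * (rho - kp.rho_c)
               / (4.0 * kp.b * (rho * (kp.a - 1.0) + kp.rho_c)))
    out = force_n / 1000.0
    return float(out) if out.ndim == 0 else out


def elastic_recovery(rho_in_die, rp: RecoveryParams):
    """In-die elastic recovery eps = eps0 ((rho - rho_c)/(1 - rho_c))^n.

    Below the onset density the recovery is zero by convention (no real
    fractional power of a negative bracket).
    """
    rho = np.asarray(rho_in_die, dtype=float)
    bracket = np.clip((rho - rp.rho_c_eps) / (1.0 - rp.rho_c_eps), 0.0, None)
    out = rp.eps0 * bracket**rp.n_exp
    return float(out) if out.ndim == 0 else out


def out_of_die_density(rho_in_die, eps_rho):
    """Out-of-die tablet density rho_tablet = rho_in_die (1 - eps)."""
    rho = np.asarray(rho_in_die, dtype=float)
    eps = np.asarray(eps_rho, dtype=float)
    if np.any(eps < 0) or np.any(eps >= 1):
        raise ValueError("elastic recovery must lie in [0, 1)")
    out = rho * (1.0 - eps)
    return float(out) if out.ndim == 0 else out


def tensile_strength(rho_tablet, sp: StrengthParams):
    """Tensile strength, MPa:

        sigma_t = sigma0 [1 - ((1 - rho)/(1 - rho_c)) exp(rho - rho_c)].

    The exponential multiplies the porosity ratio inside the bracket, so
    sigma_t vanishes at rho = rho_c and reaches sigma0 at rho = 1.
    """
    rho = np.asarray(rho_tablet, dtype=float)
    if np.any(rho < sp.rho_c_sigma):
        raise NoCoherentTabletError(
            "tablet density below the coherent-tablet threshold")
    bracket = 1.0 - ((1.0 - rho) / (1.0 - sp.rho_c_sigma)) * np.exp(
        rho - sp.rho_c_sigma)
    out = sp.sigma0 * bracket
    return float(out) if out.ndim == 0 else out


def packing_fraction(X, Y, pp: PackingParams):
    """Packing fraction phi(X, Y) = p4 (q2 X + 1)/(q1 XY + q2 X + 1) on the
    unit square of covariates X = (1-alpha)(1-(mu1/mu2)^3), Y = alpha."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    den = pp.q1 * X * Y + pp.q2 * X + 1.0
    if np.any(den <= 0):
        raise SingularSurfaceError("non-positive packing-fraction denominator")
    out = pp.p4 * (pp.q2 * X + 1.0) / den
    return float(out) if out.ndim == 0 else out


def tablet_weight(batch: GranuleBatch, pp: PackingParams, geom: ToolGeometry,
                  t_fill, rho_t: float):
    """Expected tablet weight, mg: W = phi(X, Y) rho_t rho_ribbon V_fill,
    the die-filling model with the packing fraction as filling efficacy."""
    X, Y = packing_covariates(batch.gsd)
    phi = packing_fraction(X, Y, pp)
    return phi * rho_t * batch.ribbon_density * fill_volume(geom, t_fill)


def brouwers_packing(size_ratio, alpha, ref: BrouwersReference):
    """Reference packing fraction of a bimodal hard-sphere mixture.

    ``size_ratio`` is the small-to-large mode ratio u in (0, 1]; with
    u3 = u^3 the relation reads

        phi = phi_rp [(1-a)(1-u3) + u3]
              / [C (1-a) a (u3 - 1) + (1-a)(1-u3) + u3].

    It collapses to phi_rp in the monodisperse limit (u = 1) and for C = 0,
    and exceeds phi_rp for C > 0 on moderate size ratios.  Used only as a
    qualitative reference for the fitted packing surface.
    """
    u = np.asarray(size_ratio, dtype=float)
    a = np.asarray(alpha, dtype=float)
    if np.any(u <= 0) or np.any(u > 1):
        raise ValueError("size_ratio must lie in (0, 1]")
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("alpha must lie in [0, 1]")
    u3 = u**3
    base = (1.0 - a) * (1.0 - u3) + u3
    den = ref.C * (1.0 - a) * a * (u3 - 1.0) + base
    out = ref.phi_rp * base / den
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Coupled ROMs


@dataclass(frozen=True)
class CoupledROM:
    """A tableting ROM whose parameters are rational surfaces of granule
    attributes.

    For ``cqa`` in {"force", "recovery"} the covariates are the normalized
    ribbon density X and normalized mean granule size Y; for "strength"
    the second covariate is the normalized packing fraction Z (which
    requires the fitted weight-model ``packing`` surface); for "weight"
    the packing covariates are used directly and only ``packing`` matters.

    surface1/surface2 hold the xi-parameter surfaces in the standard
    assignment: (a, rho_c) for force, (eps0, rho_c_eps) for recovery,
    (sigma0, rho_c_sigma) for strength.  ``constant`` is the Kawakita b in
    1/GPa (as conventionally reported) for force, the recovery exponent n
    for recovery, unused otherwise.
    """

    cqa: str
    geom: ToolGeometry
    surface1: RationalSurface | None = None
    surface2: RationalSurface | None = None
    r_x: float = 1.0
    r_y: float = 1.0
    constant: float | None = None
    rho_t: float = 1.558
    rho_c_rib: float = RHO_C_RIB_DEFAULT
    packing: PackingParams | None = None
    phi_min: float = 0.367
    phi_max: float = 0.631

    def __post_init__(self) -> None:
        if self.cqa not in {"weight", "force", "recovery", "strength"}:
            raise ValueError(f"unknown cqa {self.cqa!r}")
        if self.cqa in {"force", "recovery"} and self.constant is None:
            raise ValueError(f"{self.cqa} ROM requires its scalar constant")
        if self.cqa in {"weight", "strength"} and self.packing is None:
            raise ValueError(f"{self.cqa} ROM requires packing parameters")

    # -- covariates --------------------------------------------------------

    @property
    def x_variable(self) -> NormalizedVariable:
        return NormalizedVariable(lb=self.rho_c_rib, ub=1.0, r=self.r_x)

    @property
    def y_variable(self) -> NormalizedVariable:
        """Granule-size normalization; sizes in um, upper bound D/6."""
        return NormalizedVariable(lb=0.0, ub=self.geom.D / 6.0 * 1000.0,
                                  r=self.r_y)

    @property
    def z_variable(self) -> NormalizedVariable:
        return NormalizedVariable(lb=self.phi_min, ub=self.phi_max, r=self.r_y)

    def covariates(self, batch: GranuleBatch) -> tuple[float, float]:
        """Normalized covariate pair for this CQA at a granule batch."""
        if self.cqa == "weight":
            return packing_covariates(batch.gsd)
        X = normalize(batch.ribbon_density, self.x_variable)
        if self.cqa == "strength":
            Xw, Yw = packing_covariates(batch.gsd)
            phi = packing_fraction(Xw, Yw, self.packing)
            return X, normalize(phi, self.z_variable)
        return X, normalize(mean_gsd(batch.gsd), self.y_variable)

    def xi(self, batch: GranuleBatch) -> tuple[float, float]:
        """The two coupled model-parameter values at a granule batch."""
        X, Y = self.covariates(batch)
        return (eval_surface(self.surface1, X, Y),
                eval_surface(self.surface2, X, Y))

    # -- parameter objects -------------------------------------------------

    def kawakita(self, batch: GranuleBatch) -> KawakitaParams:
        a, rho_c = self.xi(batch)
        return KawakitaParams(a=a, b=self.constant / 1000.0, rho_c=rho_c)

    def recovery(self, batch: GranuleBatch) -> RecoveryParams:
        eps0, rho_c_eps = self.xi(batch)
        return RecoveryParams(eps0=eps0, rho_c_eps=rho_c_eps,
                              n_exp=self.constant)

    def strength(self, batch: GranuleBatch) -> StrengthParams:
        sigma0, rho_c_sigma = self.xi(batch)
        return StrengthParams(sigma0=sigma0, rho_c_sigma=rho_c_sigma)


def evaluate_coupled(rom: CoupledROM, batch: GranuleBatch,
                     press: PressSetpoints, W: float | None = None,
                     rho_tablet: float | None = None):
    """Evaluate a coupled ROM for one batch and press condition.

    weight  -> predicted tablet weight, mg (from the dosing position);
    force   -> main compaction force, kN (W and t_in_die set rho_in_die);
    recovery-> out-of-die tablet relative density (dimensionless);
    strength-> tensile strength, MPa (``rho_tablet`` must be supplied,
               e.g. from the recovery ROM or a measurement).
    """
    if not rom.rho_c_rib < batch.ribbon_density < 1.0:
        raise InfeasibleStateError("ribbon density outside (rho_c_rib, 1)")
    if mean_gsd(batch.gsd) >= rom.geom.D / 6.0 * 1000.0:
        raise InfeasibleStateError("mean granule size exceeds D/6")
    if rom.cqa == "weight":
        return tablet_weight(batch, rom.packing, rom.geom, press.t_fill,
                             rom.rho_t)
    if rom.cqa == "strength":
        if rho_tablet is None:
            raise ValueError("strength evaluation requires rho_tablet")
        return tensile_strength(rho_tablet, rom.strength(batch))
    if W is None:
        raise ValueError(f"{rom.cqa} evaluation requires the tablet weight W")
    v_in_die = compact_volume(rom.geom, press.t_in_die)
    rho_in_die = np.asarray(W, dtype=float) / (rom.rho_t * v_in_die)
    if rom.cqa == "force":
        return compaction_force(rho_in_die, rom.kawakita(batch), rom.geom)
    eps = elastic_recovery(rho_in_die, rom.recovery(batch))
    return out_of_die_density(rho_in_die, eps)
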