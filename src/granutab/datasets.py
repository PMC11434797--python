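"""Reference fixtures and the synthetic tableting-campaign generator.

The package ships the published study conditions as code: the six
roller-compactor granule batches (ribbon density and bimodal-Weibull GSD
parameters), the per-batch press setpoint ranges, and the reference fitted
parameter set for all four coupled ROMs.  No raw tablet-level dataset is
public, so end-to-end and parameter-recovery work runs on synthetic
campaigns generated from the reference parameters with the reported
weight variability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .coupling import RationalSurface
from .geometry import (ToolGeometry, PressSetpoints, compact_volume,
                       pitt_breaking_force, cap_volume)
from .gsd import BimodalWeibull, GranuleBatch
from .roms import (CoupledROM, PackingParams, RHO_C_RIB_DEFAULT,
                   elastic_recovery, kawakita_feasible, tablet_weight,
                   compaction_force, out_of_die_density)

__all__ = [
    "DEFAULT_GEOMETRY", "TRUE_DENSITY_GCC", "ReferenceParameters",
    "reference_parameters", "table1_batches", "table2_setpoints",
    "campaign_conditions", "NoiseSpec", "SyntheticCampaign",
    "generate_campaign",
]

log = logging.getLogger(__name__)

#: D-type doubly convex tooling of the reference press
DEFAULT_GEOMETRY = ToolGeometry(D=7.94, h=0.3302)

#: pycnometric true density of the 10% APAP / 90% MCC formulation, g/cc
TRUE_DENSITY_GCC = 1.558

# roll pressure [bar], roll gap [mm], alpha, lambda1, lambda2, k1, k2,
# printed mu1, mu2, mu_GSD [um], ribbon relative density
_TABLE1 = (
    (30, 2, 0.54, 524, 1055, 2.25, 5.32, 457, 991, 696, 0.640),
    (30, 3, 0.57, 518, 1019, 2.25, 5.43, 325, 999, 667, 0.613),
    (60, 2, 0.46, 541, 1170, 2.24, 4.98, 479, 1074, 800, 0.739),
    (60, 3, 0.58, 517, 1009, 2.26, 5.46, 458, 931, 658, 0.708),
    (90, 2, 0.44, 546, 1202, 2.23, 4.89, 484, 1102, 830, 0.803),
    (90, 3, 0.50, 533, 1114, 2.24, 5.15, 472, 1024, 747, 0.770),
)

# batch -> dosing position range [mm], main-compression thickness range [mm]
_TABLE2 = (
    ((7.0, 8.5), (2.5, 3.0)),
    ((7.0, 8.0), (2.5, 3.2)),
    ((7.5, 9.0), (2.5, 3.0)),
    ((7.0, 8.0), (2.5, 3.2)),
    ((8.0, 9.0), (3.5, 4.0)),
    ((7.0, 7.3), (3.0, 3.3)),
)


def table1_batches() -> list[GranuleBatch]:
    """The six reference granule batches.

    Mode means and the mean granule size are always recomputed from the
    Weibull (lambda, k) parameters; the published mean values are attached
    as metadata only (two of them are inconsistent with the parameters
    they accompany).
    """
    batches = []
    for (p, gap, alpha, l1, l2, k1, k2, mu1, mu2, mu, rho) in _TABLE1:
        gsd = BimodalWeibull(alpha=alpha, lambda1=l1, lambda2=l2, k1=k1, k2=k2)
        batches.append(GranuleBatch(
            ribbon_density=rho, gsd=gsd, roll_pressure=p, roll_gap=gap,
            printed_means={"mu1": mu1, "mu2": mu2, "mu_gsd": mu}))
    return batches


def table2_setpoints() -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Per-batch (dosing-position range, main-compression-thickness range),
    mm, in batch order."""
    return [tuple(row) for row in _TABLE2]


def campaign_conditions(theta: "ReferenceParameters | None" = None,
                        n_per_batch: int = 4,
                        geom: ToolGeometry = DEFAULT_GEOMETRY,
                        rho_max: float = 0.95,
                        ) -> list[tuple[int, PressSetpoints]]:
    """Press conditions spanning each batch's setpoint ranges, targeting
    evenly spaced in-die relative densities.

    The published campaign made tablets of four relative densities per
    batch but does not print the setpoints, only per-batch dosing and
    thickness ranges.  Here each batch's conditions target ``n_per_batch``
    evenly spaced in-die densities across the widest window that (i) is
    reachable inside the printed setpoint rectangle under the reference
    die-filling model, (ii) stays at or below ``rho_max``, and (iii) keeps
    the predicted out-of-die density above the coherent-tablet threshold
    with margin, so every condition supports all four CQAs.  The dosing
    position spreads across its printed range where the density target
    permits.
    """
    theta = theta if theta is not None else reference_parameters()
    roms = theta.rom_set(geom)
    area = np.pi * geom.D**2 / 4.0
    out = []
    for b, ((d_lo, d_hi), (t_lo, t_hi)) in enumerate(table2_setpoints()):
        batch = table1_batches()[b]
        rp = roms["recovery"].recovery(batch)
        sp = roms["strength"].strength(batch)
        kp = roms["force"].kawakita(batch)

        def w_of_fill(f):
            return tablet_weight(batch, theta.weight, geom, f, theta.rho_t)

        def rho_of(f, t):
            return w_of_fill(f) / (theta.rho_t * compact_volume(geom, t))

        # density window reachable inside the printed setpoint rectangle
        rho_lo = rho_of(d_lo, t_hi)
        rho_hi = min(rho_of(d_hi, t_lo), rho_max)
        # keep a coherent tablet (with margin) after elastic recovery
        grid = np.linspace(max(rho_lo, kp.rho_c + 0.05), rho_hi, 200)
        rho_tab = grid * (1.0 - elastic_recovery(grid, rp))
        ok = rho_tab >= sp.rho_c_sigma + 0.04
        if not ok.any():
            log.warning("batch %d: no feasible density window; skipped", b)
            continue
        rho_lo = float(grid[ok][0])
        targets = np.linspace(rho_lo, rho_hi, n_per_batch)
        for j, rho in enumerate(targets):
            # dosing interval compatible with this density inside the
            # thickness range (weight rises with fill, density falls with t)
            w_lo = theta.rho_t * rho * compact_volume(geom, t_lo)
            w_hi = theta.rho_t * rho * compact_volume(geom, t_hi)
            c = w_of_fill(1.0) - w_of_fill(0.5)  # slope * 0.5
            slope = 2.0 * c
            icept = w_of_fill(0.5) - 0.5 * slope
            f_lo = max(d_lo, (w_lo - icept) / slope)
            f_hi = min(d_hi, (w_hi - icept) / slope)
            frac = j / max(n_per_batch - 1, 1)
            t_fill = f_lo + frac * max(f_hi - f_lo, 0.0)
            w = w_of_fill(t_fill)
            t_in_die = (w / (theta.rho_t * rho) - cap_volume(geom)) / area
            t_in_die = float(np.clip(t_in_die, t_lo, t_hi))
            out.append((b, PressSetpoints(t_fill=float(t_fill), t_pc=5.0,
                                          t_in_die=t_in_die)))
    return out


# ---------------------------------------------------------------------------
# Reference fitted parameters


@dataclass(frozen=True)
class ReferenceParameters:
    """The reference fitted parameter set for the four coupled ROMs.

    Weight: packing surface (p4, q1, q2) with the interaction coefficient
    stored signed (q1 < 0; reports quote its magnitude) plus the packing
    bounds (phi_min, phi_max) that normalize the strength covariate Z.
    Force: pair (7,7) surfaces for (a, rho_c), exponents (rX, rY) and the
    Kawakita b in 1/GPa.  Recovery: pair (4,9) for (eps0, rho_c_eps) and
    exponent n.  Strength: pair (1,1) for (sigma0, rho_c_sigma) with
    exponents (rX, rZ).
    """

    weight: PackingParams = PackingParams(p4=0.367, q1=-6.08, q2=7.33)
    phi_min: float = 0.367
    phi_max: float = 0.631
    force_r_x: float = 10.0
    force_r_y: float = 2.39
    force_b: float = 61.39  # 1/GPa
    force_a: RationalSurface = RationalSurface(variant=7, p1=18.50, q1=27.69,
                                               p4=0.765)
    force_rho_c: RationalSurface = RationalSurface(variant=7, p1=8.73,
                                                   q1=21.38, p4=0.33)
    recovery_r_x: float = 1.0
    recovery_r_y: float = 1.0
    recovery_n: float = 0.472
    recovery_eps0: RationalSurface = RationalSurface(
        variant=4, p1=5.04, q1=18.78, p2=0.243, q2=16.10, p4=0.597)
    recovery_rho_c: RationalSurface = RationalSurface(variant=9, p4=0.334)
    strength_r_x: float = 8.26
    strength_r_z: float = 1.98
    strength_sigma0: RationalSurface = RationalSurface(
        variant=1, p1=0.33, q1=1.79, p2=124.23, q2=8.90, p3=0.18, q3=0.04,
        p4=5.90)
    strength_rho_c: RationalSurface = RationalSurface(
        variant=1, p1=50.92, q1=79.66, p2=14.82, q2=41.28, p3=0.02, q3=0.02,
        p4=0.51)
    rho_c_rib: float = RHO_C_RIB_DEFAULT
    rho_t: float = TRUE_DENSITY_GCC

    def rom(self, cqa: str, geom: ToolGeometry = DEFAULT_GEOMETRY) -> CoupledROM:
        """Build the coupled ROM for one CQA from the reference parameters."""
        common = dict(geom=geom, rho_t=self.rho_t, rho_c_rib=self.rho_c_rib,
                      phi_min=self.phi_min, phi_max=self.phi_max)
        if cqa == "weight":
            return CoupledROM(cqa="weight", packing=self.weight, **common)
        if cqa == "force":
            return CoupledROM(cqa="force", surface1=self.force_a,
                              surface2=self.force_rho_c, r_x=self.force_r_x,
                              r_y=self.force_r_y, constant=self.force_b,
                              **common)
        if cqa == "recovery":
            return CoupledROM(cqa="recovery", surface1=self.recovery_eps0,
                              surface2=self.recovery_rho_c,
                              r_x=self.recovery_r_x, r_y=self.recovery_r_y,
                              constant=self.recovery_n, **common)
        if cqa == "strength":
            return CoupledROM(cqa="strength", surface1=self.strength_sigma0,
                              surface2=self.strength_rho_c,
                              r_x=self.strength_r_x, r_y=self.strength_r_z,
                              packing=self.weight, **common)
        raise ValueError(f"unknown cqa {cqa!r}")

    def rom_set(self, geom: ToolGeometry = DEFAULT_GEOMETRY) -> dict:
        return {cqa: self.rom(cqa, geom)
                for cqa in ("weight", "force", "recovery", "strength")}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["weight"] = {"p4": self.weight.p4, "q1": self.weight.q1,
                       "q2": self.weight.q2}
        for name in ("force_a", "force_rho_c", "recovery_eps0",
                     "recovery_rho_c", "strength_sigma0", "strength_rho_c"):
            d[name] = getattr(self, name).to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceParameters":
        kw = dict(d)
        kw["weight"] = PackingParams(**kw["weight"])
        for name in ("force_a", "force_rho_c", "recovery_eps0",
                     "recovery_rho_c", "strength_sigma0", "strength_rho_c"):
            kw[name] = RationalSurface.from_dict(kw[name])
        return cls(**kw)


def reference_parameters() -> ReferenceParameters:
    """The reference fitted parameter set (versioned with the package)."""
    return ReferenceParameters()


# ---------------------------------------------------------------------------
# Synthetic campaign generation


@dataclass(frozen=True)
class NoiseSpec:
    """Relative observation noise per measured quantity.

    Tablet weight carries the reported 1.6% relative standard deviation;
    the remaining channels model instrument/process scatter on individual
    tablets and are artifact choices (the source study reports only the
    weight RSD).
    """

    weight_rsd: float = 0.016
    force_rsd: float = 0.02
    density_rsd: float = 0.02
    strength_rsd: float = 0.02

    def scaled(self, factor: float) -> "NoiseSpec":
        return NoiseSpec(*(factor * v for v in
                           (self.weight_rsd, self.force_rsd,
                            self.density_rsd, self.strength_rsd)))


@dataclass(frozen=True)
class SyntheticCampaign:
    """A generated tableting campaign plus the provenance needed to
    regenerate it bit-exactly."""

    data: pd.DataFrame
    theta: ReferenceParameters
    noise: NoiseSpec
    seed: int
    tablets_per_condition: int
    skipped_conditions: tuple = ()


CAMPAIGN_COLUMNS = ("batch_id", "t_fill_mm", "t_in_die_mm", "tablet_idx",
                    "W_mg", "F_punch_kN", "H_tablet_mm", "hardness_N")


def generate_campaign(theta: ReferenceParameters | None = None,
                      batches: list[GranuleBatch] | None = None,
                      conditions: list[tuple[int, PressSetpoints]] | None = None,
                      noise: NoiseSpec | None = None,
                      tablets_per_condition: int = 100,
                      seed: int = 0,
                      geom: ToolGeometry = DEFAULT_GEOMETRY) -> SyntheticCampaign:
    """Simulate a tableting campaign from the coupled ROM chain.

    Per condition: the mean weight comes from the die-filling model; tablet
    weights are normal draws at the weight RSD; each tablet's in-die density,
    compaction force, elastic recovery, out-of-die density and tensile
    strength follow from the ROM chain, with multiplicative observation
    noise per channel; the overall thickness is back-computed from the
    out-of-die density and the hardness through the inverse convex-tablet
    strength relation, so the table mimics raw press/tester records.

    Conditions whose mean state violates a ROM feasibility condition are
    skipped and logged.
    """
    theta = theta if theta is not None else reference_parameters()
    batches = batches if batches is not None else table1_batches()
    conditions = conditions if conditions is not None else campaign_conditions()
    noise = noise if noise is not None else NoiseSpec()
    rng = np.random.default_rng(seed)

    roms = theta.rom_set(geom)
    rows = []
    skipped = []
    m = tablets_per_condition
    for b, press in conditions:
        batch = batches[b]
        kp = roms["force"].kawakita(batch)
        rp = roms["recovery"].recovery(batch)
        sp = roms["strength"].strength(batch)
        mean_w = tablet_weight(batch, theta.weight, geom, press.t_fill,
                               theta.rho_t)
        v_in_die = compact_volume(geom, press.t_in_die)
        rho_mean = mean_w / (theta.rho_t * v_in_die)
        rho_tab_mean = rho_mean * (1.0 - elastic_recovery(rho_mean, rp))
        if (not kawakita_feasible(rho_mean, kp.a, kp.rho_c)
                or rho_tab_mean <= sp.rho_c_sigma):
            skipped.append((b, press.t_fill, press.t_in_die))
            log.warning("condition (batch %d, t_fill=%.2f, t_in_die=%.2f) "
                        "infeasible at the mean; skipped", b, press.t_fill,
                        press.t_in_die)
            continue
        w = mean_w * (1.0 + noise.weight_rsd * rng.standard_normal(m))
        rho_in_die = w / (theta.rho_t * v_in_die)
        force = compaction_force(rho_in_die, kp, geom)
        force *= 1.0 + noise.force_rsd * rng.standard_normal(m)
        eps = elastic_recovery(rho_in_die, rp)
        rho_tab = out_of_die_density(rho_in_die, eps)
        rho_tab = rho_tab * (1.0 + noise.density_rsd * rng.standard_normal(m))
        v_tab = w / (theta.rho_t * rho_tab)
        t_tab = (v_tab - cap_volume(geom)) / (np.pi * geom.D**2 / 4.0)
        h_tab = t_tab + 2.0 * geom.h
        # raw strength formula; tablets under the coherence threshold read
        # (numerically) zero hardness on the tester
        rho_eff = np.minimum(rho_tab, 1.0)
        sigma = sp.sigma0 * (1.0 - ((1.0 - rho_eff) / (1.0 - sp.rho_c_sigma))
                             * np.exp(rho_eff - sp.rho_c_sigma))
        sigma = np.clip(sigma, 0.0, None)
        sigma = sigma * (1.0 + noise.strength_rsd * rng.standard_normal(m))
        hardness = pitt_breaking_force(np.clip(sigma, 0.0, None), geom,
                                       h_tab, t_tab)
        for i in range(m):
            rows.append((b, press.t_fill, press.t_in_die, i, w[i], force[i],
                         h_tab[i], hardness[i]))
    data = pd.DataFrame(rows, columns=CAMPAIGN_COLUMNS)
    return SyntheticCampaign(data=data, theta=theta, noise=noise, seed=seed,
                             tablets_per_condition=m,
                             skipped_conditions=tuple(skipped))
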