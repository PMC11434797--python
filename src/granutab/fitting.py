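"""Constrained estimation and AIC model selection for coupled ROMs.

Each CQA (weight, force, recovery/density, strength) is fitted at
condition level: tablet-level records are averaged per tableting condition
and the sum of squared errors (SSE) is taken over conditions.  Model
quality across the variant-pair library is ranked by

    AIC = n ln(SSE/n) + 2 Np,

which is invariant (in ordering) to a uniform rescaling of the data.  The
constrained global estimation runs in three stages mirroring the reference
procedure: a population-based global search, a local derivative-free
refinement, and a multi-start polish; nonlinear data-dependent feasibility
conditions are enforced by rejection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, least_squares

from . import coupling
from .coupling import (ModelPair, RationalSurface, SingularSurfaceError,
                       count_parameters, variant_mask)
from .geometry import ToolGeometry, compact_volume, fill_volume, \
    pitt_tensile_strength
from .gsd import GranuleBatch, mean_gsd, packing_covariates
from .roms import PackingParams, RHO_C_RIB_DEFAULT, packing_fraction

__all__ = [
    "CampaignDataset", "ConstraintSet", "FitBudget", "FitResult",
    "FitTemplate", "sse", "aic", "r_squared", "fit_pair", "select_best",
    "WEIGHT_PAIR_NP",
]

log = logging.getLogger(__name__)

#: fitted parameters of the single weight-library model (p4, q1, q2)
WEIGHT_PAIR_NP = 3

# ---------------------------------------------------------------------------
# Dataset


@dataclass
class CampaignDataset:
    """Tablet-level campaign records bound to their granule batches.

    ``data`` columns: batch_id, t_fill_mm, t_in_die_mm, tablet_idx, W_mg,
    F_punch_kN, H_tablet_mm, hardness_N.  ``batches[i]`` resolves
    batch_id i.
    """

    data: pd.DataFrame
    batches: list[GranuleBatch]
    geom: ToolGeometry
    rho_t: float = 1.558

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise ValueError("campaign must contain at least one record")
        bad = set(self.data["batch_id"]) - set(range(len(self.batches)))
        if bad:
            raise ValueError(f"unresolvable batch ids: {sorted(bad)}")

    @property
    def n_conditions(self) -> int:
        return len(self.condition_means())

    def condition_means(self) -> pd.DataFrame:
        """Per-condition means of the measured and derived quantities.

        Derived per tablet before averaging: band thickness, out-of-die
        relative density (from weight and tablet volume), tensile strength
        (from hardness via the convex-tablet relation) and in-die relative
        density (from weight and the main-compression volume).
        """
        if not hasattr(self, "_cond_cache"):
            df = self.data.copy()
            g = self.geom
            t_tab = df["H_tablet_mm"] - 2.0 * g.h
            v_tab = compact_volume(g, t_tab.to_numpy())
            df["rho_tablet"] = df["W_mg"] / (self.rho_t * v_tab)
            df["sigma_t_mpa"] = pitt_tensile_strength(
                df["hardness_N"].to_numpy(), g, df["H_tablet_mm"].to_numpy(),
                t_tab.to_numpy())
            v_in = compact_volume(g, df["t_in_die_mm"].to_numpy())
            df["rho_in_die"] = df["W_mg"] / (self.rho_t * v_in)
            cond = (df.groupby(["batch_id", "t_fill_mm", "t_in_die_mm"],
                               as_index=False)
                    [["W_mg", "F_punch_kN", "rho_tablet", "sigma_t_mpa",
                      "rho_in_die"]].mean())
            self._cond_cache = cond
        return self._cond_cache


# ---------------------------------------------------------------------------
# Criteria


def aic(SSE: float, n: int, Np: int) -> float:
    """Akaike information criterion n ln(SSE/n) + 2 Np (lower is better)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if SSE < 0:
        raise ValueError("SSE must be non-negative")
    if SSE == 0.0:
        warnings.warn("perfect fit: SSE = 0 gives AIC = -inf", RuntimeWarning)
        return -np.inf
    return n * np.log(SSE / n) + 2.0 * Np


def r_squared(predictions, observations) -> float:
    """Coefficient of determination about the observed mean."""
    m = np.asarray(predictions, dtype=float)
    e = np.asarray(observations, dtype=float)
    if e.size < 2:
        raise ValueError("need at least two observations")
    tss = float(np.sum((e - e.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("zero total variance: R^2 undefined")
    return 1.0 - float(np.sum((m - e) ** 2)) / tss


# ---------------------------------------------------------------------------
# Templates, constraints, parameter vectors


@dataclass(frozen=True)
class FitTemplate:
    """Everything needed to pose one CQA's estimation problem except the
    data and the variant pair: tool geometry, formulation constants,
    normalization bounds and constraint settings."""

    cqa: str
    geom: ToolGeometry
    rho_t: float = 1.558
    rho_c_rib: float = RHO_C_RIB_DEFAULT
    rho_c_lower: float = 0.33
    rho_c_eps_ref: float = 0.334
    packing: PackingParams | None = None
    phi_min: float = 0.367
    phi_max: float = 0.631
    coeff_upper: float = 200.0

    def __post_init__(self) -> None:
        if self.cqa not in {"weight", "force", "recovery", "strength"}:
            raise ValueError(f"unknown cqa {self.cqa!r}")
        if self.cqa == "strength" and self.packing is None:
            raise ValueError("strength fitting requires the fitted "
                             "weight-model packing surface")

    @property
    def n_constants(self) -> int:
        return 1 if self.cqa in {"force", "recovery"} else 0


@dataclass(frozen=True)
class ConstraintSet:
    """Box bounds aligned with the parameter vector plus nonlinear
    feasibility predicates evaluated on (theta, data)."""

    names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    rho_c_lower: float = 0.33
    #: callables (structure, problem) -> float violation (0 when feasible)
    predicates: tuple = ()


@dataclass(frozen=True)
class FitBudget:
    """Optimizer stage budgets (configuration; stages honor the global ->
    local -> multi-start order)."""

    de_restarts: int = 3
    de_maxiter: int = 400
    de_popsize: int = 20
    de_tol: float = 0.0
    polish_starts: int = 15
    perturb: float = 0.3


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one library pair to one CQA's data."""

    cqa: str
    pair: ModelPair | None
    theta: dict
    Np: int
    SSE: float
    AIC: float
    R2: float
    feasible: bool
    n: int
    surface1: RationalSurface | None = None
    surface2: RationalSurface | None = None
    r_x: float = 1.0
    r_y: float = 1.0
    constant: float | None = None


def _surface_coeff_bounds(cqa: str, which: int, names, template: FitTemplate):
    """Box bounds for the free coefficients of one surface."""
    U = template.coeff_upper
    lo = 1e-8
    out = []
    for nm in names:
        if cqa == "recovery" and nm == "p4":
            # eps0(0,0) in (0,1) for surface 1; onset density in (rho_c_lower, 1)
            out.append((lo, 1.0 - 1e-6) if which == 1
                       else (template.rho_c_lower, 1.0 - 1e-6))
        else:
            out.append((lo, U))
    return out


def build_theta_layout(template: FitTemplate, pair: ModelPair | None):
    """Parameter-vector layout for a (CQA, pair) problem.

    Returns (names, bounds, unpack) where unpack maps a flat vector to a
    dict with surfaces, exponents and the scalar constant.
    """
    cqa = template.cqa
    if cqa == "weight":
        names = ("p4", "q1", "q2")
        bounds = ((1e-6, 1.0 - 1e-6), (-50.0, -1e-9), (1e-8, 50.0))

        def unpack(theta):
            return {"packing": PackingParams(p4=theta[0], q1=theta[1],
                                             q2=theta[2])}

        return names, bounds, unpack

    v1 = variant_mask(pair.variant_xi1)
    v2 = variant_mask(pair.variant_xi2)
    names = [f"s1_{c}" for c in v1.free_coeffs]
    bounds = _surface_coeff_bounds(cqa, 1, v1.free_coeffs, template)
    names += [f"s2_{c}" for c in v2.free_coeffs]
    bounds += _surface_coeff_bounds(cqa, 2, v2.free_coeffs, template)
    exp_free = not pair.exponents_fixed
    if exp_free:
        names += ["r_x", "r_y"]
        bounds += [(1e-3, 10.0), (1e-3, 10.0)]
    if cqa == "force":
        names += ["b"]
        bounds += [(1.0, 500.0)]  # 1/GPa
    elif cqa == "recovery":
        names += ["n"]
        bounds += [(0.05, 5.0)]
    n1, n2 = v1.n_free_coeffs, v2.n_free_coeffs

    def unpack(theta):
        c1 = dict(zip(v1.free_coeffs, theta[:n1]))
        c2 = dict(zip(v2.free_coeffs, theta[n1:n1 + n2]))
        k = n1 + n2
        if exp_free:
            r_x, r_y = theta[k], theta[k + 1]
            k += 2
        else:
            r_x = r_y = 1.0
        const = theta[k] if template.n_constants else None
        return {
            "surface1": RationalSurface(variant=pair.variant_xi1, **c1),
            "surface2": RationalSurface(variant=pair.variant_xi2, **c2),
            "r_x": float(r_x), "r_y": float(r_y), "constant": const,
        }

    return tuple(names), tuple(bounds), unpack


def constraint_set_for(template: FitTemplate,
                       pair: ModelPair | None) -> ConstraintSet:
    """Per-CQA constraint set: the box bounds of the layout plus the
    nonlinear feasibility predicates (force: positive-force conditions at
    every in-die density; recovery: p_i < q_i order constraints; strength:
    coherent-tablet threshold above the recovery onset)."""
    names, bounds, _ = build_theta_layout(template, pair)
    preds = []
    if template.cqa == "force":
        preds.append(_force_feasibility)
    elif template.cqa == "recovery":
        preds.append(_recovery_order)
    elif template.cqa == "strength":
        preds.append(_strength_threshold)
    return ConstraintSet(names=names, bounds=bounds,
                         rho_c_lower=template.rho_c_lower,
                         predicates=tuple(preds))


# ---------------------------------------------------------------------------
# Problems (data preprocessing + prediction)


class _Problem:
    """Precomputed per-condition arrays and the prediction function for one
    (template, dataset) combination."""

    def __init__(self, template: FitTemplate, data: CampaignDataset):
        self.template = template
        cond = data.condition_means()
        self.n = len(cond)
        g = data.geom
        rho_rib = np.array([data.batches[int(b)].ribbon_density
                            for b in cond["batch_id"]])
        mu = np.array([mean_gsd(data.batches[int(b)].gsd)
                       for b in cond["batch_id"]])
        xw_yw = np.array([packing_covariates(data.batches[int(b)].gsd)
                          for b in cond["batch_id"]])
        self.x_raw = (rho_rib - template.rho_c_rib) / (1.0 - rho_rib)
        d6_um = g.D / 6.0 * 1000.0
        self.y_raw = mu / (d6_um - mu)
        self.Xw, self.Yw = xw_yw[:, 0], xw_yw[:, 1]
        self.rho_rib = rho_rib
        self.v_fill = fill_volume(g, cond["t_fill_mm"].to_numpy())
        self.rho_in_die = cond["rho_in_die"].to_numpy()
        self.rho_tab = cond["rho_tablet"].to_numpy()
        self.D = g.D
        cqa = template.cqa
        self.E = {
            "weight": cond["W_mg"], "force": cond["F_punch_kN"],
            "recovery": cond["rho_tablet"], "strength": cond["sigma_t_mpa"],
        }[cqa].to_numpy()
        if cqa == "strength":
            phi = packing_fraction(self.Xw, self.Yw, template.packing)
            phi = np.clip(phi, template.phi_min,
                          template.phi_max - 1e-9)
            self.z_raw = ((phi - template.phi_min)
                          / (template.phi_max - phi))

    # each predictor returns (predictions, violation>=0)

    def predict(self, st: dict):
        cqa = self.template.cqa
        if cqa == "weight":
            pp = st["packing"]
            den = pp.q1 * self.Xw * self.Yw + pp.q2 * self.Xw + 1.0
            if np.any(den <= 1e-12):
                return None, 1.0 + float(np.sum(np.clip(1e-12 - den, 0, None)))
            phi = pp.p4 * (pp.q2 * self.Xw + 1.0) / den
            w = phi * self.template.rho_t * self.rho_rib * self.v_fill
            return w, 0.0
        X = self.x_raw ** st["r_x"]
        Y = (self.z_raw if cqa == "strength" else self.y_raw) ** st["r_y"]
        try:
            xi1 = coupling.eval_surface(st["surface1"], X, Y)
            xi2 = coupling.eval_surface(st["surface2"], X, Y)
        except SingularSurfaceError:
            return None, 1.0
        if cqa == "force":
            a, rho_c = xi1, xi2
            g1 = self.rho_in_die - rho_c
            g2 = self.rho_in_die * (a - 1.0) + rho_c
            viol = float(np.sum(np.clip(1e-9 - g1, 0, None))
                         + np.sum(np.clip(1e-9 - g2, 0, None)))
            if viol > 0:
                return None, viol
            b_mpa = st["constant"] / 1000.0
            f_kn = (np.pi * self.D**2 * g1 / (4.0 * b_mpa * g2)) / 1000.0
            return f_kn, 0.0
        if cqa == "recovery":
            eps0, rho_ce = xi1, xi2
            viol = float(np.sum(np.clip(eps0 - 1.0, 0, None))
                         + np.sum(np.clip(-eps0, 0, None))
                         + np.sum(np.clip(rho_ce - 1.0 + 1e-9, 0, None))
                         + np.sum(np.clip(self.template.rho_c_lower - rho_ce,
                                          0, None)))
            if viol > 0:
                return None, viol
            bracket = np.clip((self.rho_in_die - rho_ce) / (1.0 - rho_ce),
                              0.0, None)
            eps = eps0 * bracket ** st["constant"]
            return self.rho_in_die * (1.0 - eps), 0.0
        # strength
        sigma0, rho_cs = xi1, xi2
        viol = float(np.sum(np.clip(self.template.rho_c_eps_ref - rho_cs,
                                    0, None))
                     + np.sum(np.clip(rho_cs - 1.0 + 1e-9, 0, None))
                     + np.sum(np.clip(-sigma0, 0, None)))
        if viol > 0:
            return None, viol
        sig = sigma0 * (1.0 - ((1.0 - self.rho_tab) / (1.0 - rho_cs))
                        * np.exp(self.rho_tab - rho_cs))
        return sig, 0.0


# nonlinear predicates (violation magnitude; 0 when satisfied) -------------

def _force_feasibility(st, problem: _Problem) -> float:
    _, viol = problem.predict(st)
    return viol


def _recovery_order(st, problem: _Problem) -> float:
    s1 = st["surface1"]
    viol = 0.0
    for p_name, q_name in (("p1", "q1"), ("p2", "q2"), ("p3", "q3")):
        p, q = getattr(s1, p_name), getattr(s1, q_name)
        if p or q:
            viol += max(0.0, p - q)
    viol += max(0.0, s1.p4 - 1.0)  # p4 < q4 = 1
    return viol


def _strength_threshold(st, problem: _Problem) -> float:
    _, viol = problem.predict(st)
    return viol


# ---------------------------------------------------------------------------
# SSE and the three-stage constrained search

_INFEASIBLE = 1e12


def _objective(theta, unpack, problem, constraints):
    try:
        st = unpack(theta)
    except (ValueError, OverflowError):
        return _INFEASIBLE
    viol = 0.0
    for pred in constraints.predicates:
        viol += pred(st, problem)
    if viol > 0:
        return _INFEASIBLE * (1.0 + min(viol, 1e3))
    m, v = problem.predict(st)
    if m is None or not np.all(np.isfinite(m)):
        return _INFEASIBLE * (1.0 + min(v, 1e3))
    return float(np.sum((m - problem.E) ** 2))


def _compile_objective(template: FitTemplate, pair: ModelPair | None,
                       problem: _Problem):
    """Flat-vector objective avoiding per-call dataclass construction;
    implements the same rejection logic as :func:`_objective`."""
    cqa = template.cqa
    E = problem.E
    if cqa == "weight":
        Xw, Yw = problem.Xw, problem.Yw
        base = template.rho_t * problem.rho_rib * problem.v_fill

        def obj(theta):
            p4, q1, q2 = theta
            den = q1 * Xw * Yw + q2 * Xw + 1.0
            if np.any(den <= 1e-12):
                return _INFEASIBLE * 2.0
            m = p4 * (q2 * Xw + 1.0) / den * base
            return float(np.sum((m - E) ** 2))

        return obj

    v1 = variant_mask(pair.variant_xi1)
    v2 = variant_mask(pair.variant_xi2)
    idx1 = np.array([coupling.COEFF_NAMES.index(c) for c in v1.free_coeffs])
    idx2 = np.array([coupling.COEFF_NAMES.index(c) for c in v2.free_coeffs])
    n1, n2 = len(idx1), len(idx2)
    exp_free = not pair.exponents_fixed
    k_exp = n1 + n2
    k_const = k_exp + (2 if exp_free else 0)
    x_raw = problem.x_raw
    y_raw = problem.z_raw if cqa == "strength" else problem.y_raw
    rho_in = problem.rho_in_die
    rho_tab = problem.rho_tab
    rho_c_lower = template.rho_c_lower
    rho_c_eps_ref = template.rho_c_eps_ref
    area = np.pi * problem.D**2 / 4.0

    def surfaces(theta):
        c1 = np.zeros(7)
        c1[idx1] = theta[:n1]
        c2 = np.zeros(7)
        c2[idx2] = theta[n1:n1 + n2]
        if exp_free:
            X = x_raw ** theta[k_exp]
            Y = y_raw ** theta[k_exp + 1]
        else:
            X, Y = x_raw, y_raw
        XY = X * Y
        f1 = ((c1[0] * XY + c1[1] * X + c1[2] * Y + c1[3])
              / (c1[4] * XY + c1[5] * X + c1[6] * Y + 1.0))
        f2 = ((c2[0] * XY + c2[1] * X + c2[2] * Y + c2[3])
              / (c2[4] * XY + c2[5] * X + c2[6] * Y + 1.0))
        return c1, c2, f1, f2

    if cqa == "force":

        def obj(theta):
            _, _, a, rho_c = surfaces(theta)
            g1 = rho_in - rho_c
            g2 = rho_in * (a - 1.0) + rho_c
            viol = (np.sum(np.clip(1e-9 - g1, 0, None))
                    + np.sum(np.clip(1e-9 - g2, 0, None)))
            if viol > 0:
                return _INFEASIBLE * (1.0 + min(float(viol), 1e3))
            m = (np.pi * problem.D**2 * g1
                 / (4.0 * theta[k_const] / 1000.0 * g2)) / 1000.0
            return float(np.sum((m - E) ** 2))

    elif cqa == "recovery":

        def obj(theta):
            c1, _, eps0, rho_ce = surfaces(theta)
            viol = 0.0
            # order constraints p_i < q_i (q4 = 1) keep eps0 in (0, 1)
            for i in range(3):
                if c1[i] or c1[4 + i]:
                    viol += max(0.0, c1[i] - c1[4 + i])
            viol += max(0.0, c1[3] - 1.0)
            viol += float(np.sum(np.clip(eps0 - 1.0, 0, None))
                          + np.sum(np.clip(-eps0, 0, None))
                          + np.sum(np.clip(rho_ce - 1.0 + 1e-9, 0, None))
                          + np.sum(np.clip(rho_c_lower - rho_ce, 0, None)))
            if viol > 0:
                return _INFEASIBLE * (1.0 + min(viol, 1e3))
            bracket = np.clip((rho_in - rho_ce) / (1.0 - rho_ce), 0.0, None)
            m = rho_in * (1.0 - eps0 * bracket ** theta[k_const])
            return float(np.sum((m - E) ** 2))

    else:  # strength

        def obj(theta):
            _, _, sigma0, rho_cs = surfaces(theta)
            viol = float(np.sum(np.clip(rho_c_eps_ref - rho_cs, 0, None))
                         + np.sum(np.clip(rho_cs - 1.0 + 1e-9, 0, None))
                         + np.sum(np.clip(-sigma0, 0, None)))
            if viol > 0:
                return _INFEASIBLE * (1.0 + min(viol, 1e3))
            m = sigma0 * (1.0 - ((1.0 - rho_tab) / (1.0 - rho_cs))
                          * np.exp(rho_tab - rho_cs))
            return float(np.sum((m - E) ** 2))

    return obj


def _compile_residuals(template: FitTemplate, pair: ModelPair | None,
                       problem: _Problem):
    """Residual vector for the local least-squares stages: model errors
    plus smooth penalty residuals for the feasibility conditions (so the
    trust-region solver can approach the boundary without the hard
    rejection discontinuity)."""
    cqa = template.cqa
    E = problem.E
    PEN = 1e4

    def soft(g):  # continuous penalty residual for constraint g >= 0
        return np.sqrt(np.clip(-g, 0.0, None)) * PEN

    if cqa == "weight":
        Xw, Yw = problem.Xw, problem.Yw
        base = template.rho_t * problem.rho_rib * problem.v_fill

        def resid(theta):
            p4, q1, q2 = theta
            den = q1 * Xw * Yw + q2 * Xw + 1.0
            m = p4 * (q2 * Xw + 1.0) / np.clip(den, 1e-9, None) * base
            return np.concatenate([m - E, soft(den - 1e-9)])

        return resid

    v1 = variant_mask(pair.variant_xi1)
    v2 = variant_mask(pair.variant_xi2)
    idx1 = np.array([coupling.COEFF_NAMES.index(c) for c in v1.free_coeffs])
    idx2 = np.array([coupling.COEFF_NAMES.index(c) for c in v2.free_coeffs])
    n1, n2 = len(idx1), len(idx2)
    exp_free = not pair.exponents_fixed
    k_exp = n1 + n2
    k_const = k_exp + (2 if exp_free else 0)
    x_raw = problem.x_raw
    y_raw = problem.z_raw if cqa == "strength" else problem.y_raw
    rho_in = problem.rho_in_die
    rho_tab = problem.rho_tab
    rho_c_lower = template.rho_c_lower
    rho_c_eps_ref = template.rho_c_eps_ref

    def surfaces(theta):
        c1 = np.zeros(7)
        c1[idx1] = theta[:n1]
        c2 = np.zeros(7)
        c2[idx2] = theta[n1:n1 + n2]
        if exp_free:
            X = x_raw ** theta[k_exp]
            Y = y_raw ** theta[k_exp + 1]
        else:
            X, Y = x_raw, y_raw
        XY = X * Y
        f1 = ((c1[0] * XY + c1[1] * X + c1[2] * Y + c1[3])
              / (c1[4] * XY + c1[5] * X + c1[6] * Y + 1.0))
        f2 = ((c2[0] * XY + c2[1] * X + c2[2] * Y + c2[3])
              / (c2[4] * XY + c2[5] * X + c2[6] * Y + 1.0))
        return c1, c2, f1, f2

    if cqa == "force":
        D = problem.D

        def resid(theta):
            _, _, a, rho_c = surfaces(theta)
            g1 = rho_in - rho_c
            g2 = rho_in * (a - 1.0) + rho_c
            m = (np.pi * D**2 * np.clip(g1, 1e-12, None)
                 / (4.0 * theta[k_const] / 1000.0
                    * np.clip(g2, 1e-12, None))) / 1000.0
            return np.concatenate([m - E, soft(g1 - 1e-9), soft(g2 - 1e-9)])

    elif cqa == "recovery":

        def resid(theta):
            c1, _, eps0, rho_ce = surfaces(theta)
            order = soft(np.array([c1[4 + i] - c1[i] for i in range(3)
                                   if c1[i] or c1[4 + i]] + [1.0 - c1[3]]))
            rho_ce_s = np.clip(rho_ce, None, 1.0 - 1e-6)
            bracket = np.clip((rho_in - rho_ce_s) / (1.0 - rho_ce_s), 0, None)
            m = rho_in * (1.0 - np.clip(eps0, 0.0, 1.0)
                          * bracket ** theta[k_const])
            return np.concatenate([
                m - E, order, soft(eps0), soft(1.0 - eps0),
                soft(rho_ce - rho_c_lower), soft(1.0 - 1e-9 - rho_ce)])

    else:  # strength

        def resid(theta):
            _, _, sigma0, rho_cs = surfaces(theta)
            rho_cs_s = np.clip(rho_cs, None, 1.0 - 1e-6)
            m = np.clip(sigma0, 0.0, None) * (
                1.0 - ((1.0 - rho_tab) / (1.0 - rho_cs_s))
                * np.exp(rho_tab - rho_cs_s))
            return np.concatenate([
                m - E, soft(rho_cs - rho_c_eps_ref),
                soft(1.0 - 1e-9 - rho_cs), soft(sigma0)])

    return resid


def sse(template: FitTemplate, pair: ModelPair | None, theta,
        data: CampaignDataset, constraints: ConstraintSet | None = None) -> float:
    """Sum of squared condition-level errors for a parameter vector; +inf
    when a nonlinear feasibility predicate is violated (rejection)."""
    _, bounds, unpack = build_theta_layout(template, pair)
    constraints = constraints or constraint_set_for(template, pair)
    problem = _Problem(template, data)
    val = _objective(np.asarray(theta, dtype=float), unpack, problem,
                     constraints)
    return np.inf if val >= _INFEASIBLE else val


def fit_pair(template: FitTemplate, pair: ModelPair | None,
             data: CampaignDataset, constraints: ConstraintSet | None = None,
             budget: FitBudget | None = None, seed: int = 0) -> FitResult:
    """Fit one library pair with the three-stage constrained search.

    Stage 1 is a population-based global search (differential evolution)
    over the box bounds; stage 2 refines the stage-1 best with a bounded
    derivative-free local method; stage 3 polishes with multi-start local
    searches around the incumbent.  Deterministic for a fixed seed.
    Nonlinear feasibility predicates are enforced by rejection throughout.
    """
    budget = budget or FitBudget()
    names, bounds, unpack = build_theta_layout(template, pair)
    default_cons = constraint_set_for(template, pair)
    constraints = constraints or default_cons
    bounds = constraints.bounds
    problem = _Problem(template, data)
    rng = np.random.default_rng(seed)
    fast = _compile_objective(template, pair, problem)
    extra = [p for p in constraints.predicates
             if p not in default_cons.predicates]
    if extra:
        def obj(th):
            try:
                st = unpack(th)
            except (ValueError, OverflowError):
                return _INFEASIBLE
            viol = sum(p(st, problem) for p in extra)
            if viol > 0:
                return _INFEASIBLE * (1.0 + min(viol, 1e3))
            return fast(th)
    else:
        obj = fast
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    resid = _compile_residuals(template, pair, problem)

    def local(x0):
        """Bounded trust-region least-squares refinement; the hard
        objective gates acceptance so rejection semantics are preserved."""
        x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)
        try:
            ls = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                               xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except (ValueError, FloatingPointError):
            return x0, np.inf
        return ls.x, obj(ls.x)

    # stage 1: restarted global population search
    best_x, best_f = None, np.inf
    for _ in range(budget.de_restarts):
        de = differential_evolution(
            obj, bounds=list(bounds), seed=int(rng.integers(2**31 - 1)),
            maxiter=budget.de_maxiter, popsize=budget.de_popsize,
            tol=budget.de_tol, init="sobol", polish=False,
            updating="deferred", mutation=(0.5, 1.5), recombination=0.9)
        if de.fun < best_f:
            best_x, best_f = de.x, de.fun

    # stage 2: local refinement from the stage-1 best
    x, f = local(best_x)
    if f < best_f:
        best_x, best_f = x, f

    # stage 3: multi-start polish around the incumbent
    span = hi - lo
    for _ in range(budget.polish_starts):
        x0 = best_x + budget.perturb * span * rng.standard_normal(len(bounds))
        x, f = local(x0)
        if f < best_f:
            best_x, best_f = x, f

    feasible = best_f < _INFEASIBLE
    st = unpack(best_x) if feasible else {}
    if feasible:
        m, _ = problem.predict(st)
        SSE = float(np.sum((m - problem.E) ** 2))
        R2 = r_squared(m, problem.E)
    else:
        SSE, R2 = np.inf, -np.inf
        log.warning("no feasible point found for %s pair %s", template.cqa,
                    pair)
    Np = (WEIGHT_PAIR_NP if template.cqa == "weight"
          else count_parameters(pair, template.n_constants))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        A = aic(SSE, problem.n, Np) if feasible else np.inf
    return FitResult(
        cqa=template.cqa, pair=pair, theta=dict(zip(names, best_x)),
        Np=Np, SSE=SSE, AIC=A, R2=R2, feasible=feasible, n=problem.n,
        surface1=st.get("surface1"), surface2=st.get("surface2"),
        r_x=st.get("r_x", 1.0), r_y=st.get("r_y", 1.0),
        constant=st.get("constant"))


def select_best(template: FitTemplate, library: list[ModelPair],
                data: CampaignDataset,
                constraints: ConstraintSet | None = None,
                budget: FitBudget | None = None,
                seed: int = 0) -> list[FitResult]:
    """Fit every library pair and rank ascending by AIC (ties: smaller Np,
    then lexicographic pair id).  The first entry is the selected model."""
    if not library:
        raise ValueError("model library must be non-empty")
    results = []
    for i, pair in enumerate(library):
        results.append(fit_pair(template, pair, data, constraints=constraints,
                                budget=budget, seed=seed + i))
        log.info("fitted %s pair %s: AIC=%.4g SSE=%.4g", template.cqa,
                 pair.astuple() if pair else "-", results[-1].AIC,
                 results[-1].SSE)
    return sorted(results, key=lambda r: (r.AIC, r.Np,
                                          r.pair.astuple() if r.pair else ()))
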