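"""Structured configuration, delimited-text campaign I/O and reports.

All tabular files are comma-separated UTF-8 with a header row and '.' as
the decimal mark.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import pandas as pd
import yaml

from .datasets import (DEFAULT_GEOMETRY, TRUE_DENSITY_GCC, CAMPAIGN_COLUMNS,
                       table1_batches)
from .fitting import CampaignDataset, FitBudget, FitResult
from .geometry import ToolGeometry
from .roms import RHO_C_RIB_DEFAULT

__all__ = ["RunConfig", "ConfigError", "load_config", "read_campaign",
           "write_campaign", "report_ranking", "read_batches",
           "write_batches"]

log = logging.getLogger(__name__)

BATCH_COLUMNS = ("roll_pressure_bar", "roll_gap_mm", "alpha", "lambda1_um",
                 "lambda2_um", "k1", "k2", "ribbon_density")


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def _strict(cls, mapping: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**mapping)


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration: tool geometry, formulation constants,
    normalization bounds, optimizer budgets, noise and seed."""

    tool_D_mm: float = DEFAULT_GEOMETRY.D
    tool_h_mm: float = DEFAULT_GEOMETRY.h
    true_density_gcc: float = TRUE_DENSITY_GCC
    rho_c_rib: float = RHO_C_RIB_DEFAULT
    rho_c_lower: float = 0.33
    phi_min: float = 0.367
    phi_max: float = 0.631
    weight_rsd: float = 0.016
    observation_rsd: float = 0.02
    n_mc_samples: int = 10_000
    tablets_per_condition: int = 100
    seed: int = 0
    optimizer: FitBudget = field(default_factory=FitBudget)

    @property
    def geometry(self) -> ToolGeometry:
        return ToolGeometry(D=self.tool_D_mm, h=self.tool_h_mm)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        mapping = dict(mapping)
        opt = mapping.pop("optimizer", None)
        cfg_kwargs = {}
        if opt is not None:
            cfg_kwargs["optimizer"] = _strict(FitBudget, opt)
        known = {f.name for f in fields(cls)} - {"optimizer"}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown RunConfig keys: {sorted(unknown)}")
        cfg = cls(**mapping, **cfg_kwargs)
        if cfg.tool_D_mm <= 0 or cfg.tool_h_mm < 0:
            raise ConfigError("invalid tool geometry")
        return cfg

    def digest(self) -> str:
        """Stable short hash of the configuration, for output provenance."""
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration (defaults when path is None)."""
    if path is None:
        return RunConfig()
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    return RunConfig.from_mapping(raw)


def read_campaign(path: str | Path, batches=None,
                  geom: ToolGeometry = DEFAULT_GEOMETRY,
                  rho_t: float = TRUE_DENSITY_GCC) -> CampaignDataset:
    """Read a tablet-level campaign CSV into a validated dataset.

    Column schema: batch_id, t_fill_mm, t_in_die_mm, tablet_idx, W_mg,
    F_punch_kN, H_tablet_mm, hardness_N.  Errors carry data line numbers
    (header = line 1).
    """
    batches = batches if batches is not None else table1_batches()
    df = pd.read_csv(path, comment="#")
    missing = set(CAMPAIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df[list(CAMPAIGN_COLUMNS)]
    for col in CAMPAIGN_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise ValueError(f"{path}:{line}: non-numeric value in {col!r}")
        df[col] = vals
    for col in ("W_mg", "H_tablet_mm", "t_fill_mm", "t_in_die_mm"):
        neg = df[col] <= 0
        if neg.any():
            line = int(neg.idxmax()) + 2
            raise ValueError(f"{path}:{line}: non-positive {col!r}")
    unknown = set(df["batch_id"].astype(int)) - set(range(len(batches)))
    if unknown:
        raise ValueError(f"{path}: unknown batch ids {sorted(unknown)}")
    df["batch_id"] = df["batch_id"].astype(int)
    df["tablet_idx"] = df["tablet_idx"].astype(int)
    ds = CampaignDataset(data=df, batches=batches, geom=geom, rho_t=rho_t)
    log.info("read %d records over %d conditions from %s", len(df),
             ds.n_conditions, path)
    return ds


def write_campaign(dataset: CampaignDataset | pd.DataFrame,
                   path: str | Path) -> None:
    df = dataset.data if isinstance(dataset, CampaignDataset) else dataset
    df.to_csv(path, index=False)


def read_batches(path: str | Path):
    """Read granule batches from a delimited file with the BATCH_COLUMNS
    schema; means are recomputed from the Weibull parameters."""
    from .gsd import BimodalWeibull, GranuleBatch
    df = pd.read_csv(path)
    missing = set(BATCH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        gsd = BimodalWeibull(alpha=row["alpha"], lambda1=row["lambda1_um"],
                             lambda2=row["lambda2_um"], k1=row["k1"],
                             k2=row["k2"])
        out.append(GranuleBatch(ribbon_density=row["ribbon_density"],
                                gsd=gsd,
                                roll_pressure=row["roll_pressure_bar"],
                                roll_gap=row["roll_gap_mm"]))
    return out


def write_batches(batches, path: str | Path) -> None:
    rows = [(b.roll_pressure, b.roll_gap, b.gsd.alpha, b.gsd.lambda1,
             b.gsd.lambda2, b.gsd.k1, b.gsd.k2, b.ribbon_density)
            for b in batches]
    pd.DataFrame(rows, columns=list(BATCH_COLUMNS)).to_csv(path, index=False)


def report_ranking(results: list[FitResult], top: int = 5) -> pd.DataFrame:
    """Ranked model table (pair, Np, SSE, R2, AIC), ascending AIC with ties
    broken by smaller Np; the top-k rows are returned."""
    if not results:
        raise ValueError("no results to report")
    ordered = sorted(results, key=lambda r: (r.AIC, r.Np,
                                             r.pair.astuple() if r.pair
                                             else ()))
    rows = [{"pair": "x".join(map(str, r.pair.astuple())) if r.pair else
             "weight", "Np": r.Np, "SSE": r.SSE, "R2": r.R2, "AIC": r.AIC}
            for r in ordered[:top]]
    return pd.DataFrame(rows)
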