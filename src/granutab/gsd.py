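"""Bimodal Weibull granule-size distributions.

The granule population produced by ribbon milling is described by a
two-component Weibull mixture: a small mode (fraction ``alpha``, scale
``lambda1``, shape ``k1``) and a large mode (scale ``lambda2``, shape
``k2``).  Sizes are in micrometres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as _gamma
from scipy.stats import weibull_min

__all__ = ["BimodalWeibull", "GranuleBatch", "pdf", "mode_means", "mean_gsd",
           "sample", "packing_covariates"]


@dataclass(frozen=True)
class BimodalWeibull:
    """Five-parameter Weibull mixture for a granule size distribution.

    Mode 1 is the small mode: its mean must not exceed the large-mode mean.
    """

    alpha: float
    lambda1: float
    lambda2: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("scale parameters must be positive")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("shape parameters must be positive")
        mu1, mu2 = mode_means(self)
        if mu1 > mu2:
            raise ValueError(
                f"mode 1 must be the small mode (mu1={mu1:.1f} > mu2={mu2:.1f})"
            )


@dataclass(frozen=True)
class GranuleBatch:
    """One roller-compactor condition: ribbon relative density plus the
    granule size distribution it produced.  Roll pressure (bar) and roll
    gap (mm) are upstream metadata."""

    ribbon_density: float
    gsd: BimodalWeibull
    roll_pressure: float | None = None
    roll_gap: float | None = None
    printed_means: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.ribbon_density < 1.0:
            raise ValueError("ribbon relative density must lie in (0, 1)")


def pdf(gsd: BimodalWeibull, x):
    """Mixture density at size x (1/um)."""
    x = np.asarray(x, dtype=float)
    f1 = weibull_min.pdf(x, gsd.k1, scale=gsd.lambda1)
    f2 = weibull_min.pdf(x, gsd.k2, scale=gsd.lambda2)
    out = gsd.alpha * f1 + (1.0 - gsd.alpha) * f2
    return float(out) if out.ndim == 0 else out


def mode_means(gsd: BimodalWeibull) -> tuple[float, float]:
    """Mean size of each mode: mu_i = lambda_i * Gamma(1 + 1/k_i), um."""
    mu1 = gsd.lambda1 * _gamma(1.0 + 1.0 / gsd.k1)
    mu2 = gsd.lambda2 * _gamma(1.0 + 1.0 / gsd.k2)
    return float(mu1), float(mu2)


def mean_gsd(gsd: BimodalWeibull) -> float:
    """Mixture mean granule size mu_GSD = alpha*mu1 + (1-alpha)*mu2, um."""
    mu1, mu2 = mode_means(gsd)
    return gsd.alpha * mu1 + (1.0 - gsd.alpha) * mu2


def sample(gsd: BimodalWeibull, n: int, seed) -> np.ndarray:
    """Draw n granule sizes (um) from the mixture.

    Component membership is Bernoulli(alpha); sizes within a component are
    inverse-CDF Weibull draws.  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    small = rng.random(n) < gsd.alpha
    u = rng.random(n)
    out = np.where(
        small,
        weibull_min.ppf(u, gsd.k1, scale=gsd.lambda1),
        weibull_min.ppf(u, gsd.k2, scale=gsd.lambda2),
    )
    return out


def packing_covariates(gsd: BimodalWeibull) -> tuple[float, float]:
    """Normalized packing-model covariates (X, Y) for the weight model.

    X = (1 - alpha) * (1 - (mu1/mu2)^3) captures the size-ratio effect of a
    bimodal packing; Y = alpha is the small-mode fraction.  Both lie in
    [0, 1] when mode 1 is the small mode.
    """
    mu1, mu2 = mode_means(gsd)
    if mu2 <= 0:
        raise ValueError("large-mode mean must be positive")
    if mu1 > mu2:
        raise ValueError("mode ordering violated: mu1 > mu2")
    X = (1.0 - gsd.alpha) * (1.0 - (mu1 / mu2) ** 3)
    Y = gsd.alpha
    return X, Y
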