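"""Salt-corrected cell dry weight (CDW) per OD600·mL.

Cells grown at seawater osmolarity lyse when washed in water, so pellets are
washed in NaCl solution instead and the residual salt must be corrected for.
With x the dry pellet weight (mg), y the wet pellet weight (mg), w the
harvested culture amount (OD600·mL), rho the wash salinity (mg NaCl per mg
water) and beta the assumed cellular water per CDW (mg/mg), the mass balance

    alpha * w = x - rho * z          (dry weight = solids minus residual salt)
    z = y - x - beta * alpha * w     (extracellular water in the wet pellet)

gives the CDW conversion factor

    alpha = (x * (1 + rho) - rho * y) / (w * (1 - rho * beta)).

Because rho is small (~0.03 for 0.52 M NaCl), alpha depends only weakly on
the assumed beta.  Rearranged, y is linear in x across pellets that differ
only in added-back wash solution, so an ordinary-least-squares fit of y on x
estimates rho from the slope and alpha from the x-intercept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "PelletWeighing",
    "AddBackSeries",
    "CdwEstimate",
    "alpha_direct",
    "beta_max",
    "alpha_beta_curve",
    "alpha_regression",
    "DEFAULT_BETA",
]

#: Cellular water per CDW assumed for rod-shaped Gram-negative cells (mg/mg),
#: with a +/-1 band propagated into the reported alpha interval.
DEFAULT_BETA = 2.0
BETA_BAND = 1.0


@dataclass(frozen=True)
class PelletWeighing:
    """One dry/wet pellet record. Units: mg, OD600·mL; rho dimensionless."""

    x: float  # dry pellet weight
    y: float  # wet pellet weight
    w: float  # harvested culture, OD600·mL
    rho: float  # wash salinity, mg NaCl / mg water
    beta: float = DEFAULT_BETA  # assumed cellular water / CDW

    def __post_init__(self) -> None:
        if not self.x > 0:
            raise ValueError("dry weight x must be positive")
        if not self.y > self.x:
            raise ValueError("wet weight y must exceed dry weight x")
        if not self.w > 0:
            raise ValueError("harvested amount w must be positive")
        if not (0 <= self.rho < 1):
            raise ValueError("wash salinity rho must be in [0, 1)")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if self.rho * self.beta >= 1:
            raise ValueError("rho * beta must be < 1")


@dataclass(frozen=True)
class AddBackSeries:
    """Pellets from aliquots of one culture with different added-back wash volumes."""

    pellets: Tuple[Tuple[float, float], ...]  # (x, y) in mg
    w: float  # OD600·mL per aliquot (same for all)
    beta: float = DEFAULT_BETA

    def __post_init__(self) -> None:
        if len(self.pellets) < 2:
            raise ValueError("need at least two pellets")
        for x, y in self.pellets:
            if not (y > x > 0):
                raise ValueError("each pellet needs y > x > 0")
        if not self.w > 0:
            raise ValueError("w must be positive")


@dataclass(frozen=True)
class CdwEstimate:
    alpha: float  # mg CDW per OD600·mL
    beta_max: float  # y/x - 1 upper bound on beta
    rho_hat: Optional[float] = None
    r_squared: Optional[float] = None
    #: alpha evaluated at beta +/- 1, reported as an uncertainty interval
    alpha_interval: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")


def beta_max(p: PelletWeighing) -> float:
    """Upper bound on cellular water per CDW set by the pellet itself: y/x - 1."""
    return p.y / p.x - 1.0


def _alpha(x: float, y: float, w: float, rho: float, beta: float) -> float:
    return (x * (1.0 + rho) - rho * y) / (w * (1.0 - rho * beta))


def alpha_direct(p: PelletWeighing) -> CdwEstimate:
    """Estimate alpha (mg CDW per OD600·mL) from a single pellet weighing."""
    bmax = beta_max(p)
    # at rho = 0 the estimate reduces to x/w and beta drops out entirely;
    # beta == beta_max is the valid boundary of zero extracellular water
    if p.rho > 0 and p.beta > bmax * (1 + 1e-9):
        raise ValueError(
            f"assumed cellular water exceeds total pellet water (beta={p.beta} >= beta_max={bmax:.4g})"
        )
    numerator = p.x * (1.0 + p.rho) - p.rho * p.y
    if numerator <= 0:
        raise ValueError("inconsistent record: wash salt heavier than pellet solids")
    a = numerator / (p.w * (1.0 - p.rho * p.beta))
    lo = _alpha(p.x, p.y, p.w, p.rho, max(0.0, p.beta - BETA_BAND))
    hi_beta = min(p.beta + BETA_BAND, bmax * (1 - 1e-12))
    hi = _alpha(p.x, p.y, p.w, p.rho, hi_beta)
    return CdwEstimate(alpha=a, beta_max=bmax, alpha_interval=(min(lo, hi), max(lo, hi)))


def alpha_beta_curve(p: PelletWeighing, betas: Sequence[float]) -> List[Tuple[float, float]]:
    """Evaluate alpha at each assumed beta; monotone nondecreasing in beta.

    At rho = 0 the curve is constant (no salt to correct).  For small rho the
    relative change over a beta interval is ~ rho*Δbeta/(1 - rho*beta), which
    is what makes the conversion factor robust to the assumed water content.
    """
    bmax = beta_max(p)
    out = []
    for b in betas:
        if not (0 <= b < bmax):
            raise ValueError(f"beta={b} outside [0, beta_max={bmax:.4g})")
        out.append((float(b), _alpha(p.x, p.y, p.w, p.rho, b)))
    return out


def alpha_regression(s: AddBackSeries) -> CdwEstimate:
    """Estimate (rho, alpha) by OLS of wet weight y on dry weight x.

    Across aliquots differing only in added-back wash solution, y is linear
    in x with slope 1 + 1/rho; the x-intercept x0 recovers
    alpha = x0 * (1 + rho) / ((1 - rho*beta) * w).
    """
    xs = np.array([p[0] for p in s.pellets], dtype=float)
    ys = np.array([p[1] for p in s.pellets], dtype=float)
    if np.ptp(xs) == 0:
        raise ValueError("identical dry weights: slope undefined")
    slope, intercept = np.polyfit(xs, ys, 1)
    if slope <= 1:
        raise ValueError(f"fitted slope {slope:.4g} <= 1 implies rho <= 0; inconsistent series")
    rho_hat = 1.0 / (slope - 1.0)
    x0 = -intercept / slope
    alpha = x0 * (1.0 + rho_hat) / ((1.0 - rho_hat * s.beta) * s.w)
    resid = ys - (slope * xs + intercept)
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    bmax = min(y / x - 1.0 for x, y in s.pellets)
    return CdwEstimate(alpha=alpha, beta_max=bmax, rho_hat=rho_hat, r_squared=r2)
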