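"""Growth and maintenance energetics (GAM, NGAM) from batch-culture series.

Batch cultures on different carbon sources span a range of growth rates.
For each culture, plotting substrate and acetate concentrations against
OD600 gives consumption and excretion yields (slopes, converted to mM of
carbon atoms per OD600); their difference times the growth rate is the
carbon utilization rate — carbon going into biomass or burned for energy.
Across cultures, carbon utilization is linear in growth rate: the
y-intercept is the carbon spent on maintenance at zero growth, which FBA
(maximizing ATP production at zero biomass flux under the pinned carbon
influx) converts into the non-growth-associated maintenance (NGAM, a lower
bound on an ATP-hydrolysis flux); the growth-associated maintenance (GAM,
an ATP term in the biomass reaction) is then fitted so FBA-predicted growth
rates under the measured uptake/secretion fluxes match the observed ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .model_core import (
    FluxStatus,
    MetabolicModel,
    ModelError,
    fba,
    set_medium,
)

__all__ = [
    "BatchSeries",
    "YieldEstimate",
    "MaintenanceLine",
    "MaintenanceParams",
    "growth_rate",
    "yields",
    "carbon_utilization",
    "maintenance_line",
    "ngam_from_intercept",
    "set_gam",
    "fit_gam",
    "estimate_maintenance",
    "SubstrateInfo",
]

ACETATE_CARBONS = 2


@dataclass(frozen=True)
class BatchSeries:
    """Timed OD600/substrate/acetate measurements for one exponential batch culture."""

    times: Tuple[float, ...]  # h
    od: Tuple[float, ...]
    substrate_mM: Tuple[float, ...]
    acetate_mM: Tuple[float, ...]
    substrate_carbons: int
    medium_label: str = ""

    def __post_init__(self) -> None:
        n = len(self.times)
        if n < 4:
            raise ValueError("need at least 4 time points")
        if not all(len(v) == n for v in (self.od, self.substrate_mM, self.acetate_mM)):
            raise ValueError("all channels must have the same length")
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        if any(o <= 0 for o in self.od):
            raise ValueError("OD readings must be positive")
        if self.substrate_carbons < 1:
            raise ValueError("substrate_carbons must be >= 1")


@dataclass(frozen=True)
class YieldEstimate:
    growth_rate: float  # 1/h
    consumption_yield: float  # mM-C per OD600
    excretion_yield: float  # mM-C per OD600
    r_squared: Mapping[str, Optional[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.consumption_yield < 0 or self.excretion_yield < 0:
            raise ValueError("yields must be nonnegative")
        if not self.growth_rate > 0:
            raise ValueError("growth rate must be positive")


@dataclass(frozen=True)
class MaintenanceLine:
    slope: float  # mM-C / OD600  (per unit growth rate)
    intercept: float  # mM-C / OD600 / h


@dataclass(frozen=True)
class MaintenanceParams:
    ngam: float  # mmol ATP / gCDW / h
    gam: float  # mmol ATP / gCDW
    cdw_conversion: float  # mg CDW / (OD600·mL) used for unit conversion
    residuals: Tuple[float, ...] = ()  # per-observation mu_FBA - mu_obs at the fit

    def __post_init__(self) -> None:
        if self.ngam < 0 or self.gam < 0:
            raise ValueError("maintenance parameters must be nonnegative")


def _ols(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss if ss > 0 else 1.0
    return float(slope), float(intercept), r2


def growth_rate(s: BatchSeries) -> float:
    """Exponential growth rate: OLS slope of ln(OD600) against time."""
    slope, _, _ = _ols(np.asarray(s.times), np.log(np.asarray(s.od)))
    return slope


def yields(s: BatchSeries) -> YieldEstimate:
    """Consumption and excretion yields (mM-C per OD600) from concentration-vs-OD slopes."""
    od = np.asarray(s.od)
    sub = np.asarray(s.substrate_mM)
    ace = np.asarray(s.acetate_mM)
    s_slope, _, s_r2 = _ols(od, sub)
    if s_slope > 1e-9:
        raise ValueError(f"substrate increasing over the series (slope {s_slope:.4g} mM/OD)")
    consumption = -s_slope * s.substrate_carbons
    if np.allclose(ace, 0.0):
        excretion, a_r2 = 0.0, None
    else:
        a_slope, _, a_r2 = _ols(od, ace)
        excretion = max(0.0, a_slope * ACETATE_CARBONS)
    return YieldEstimate(
        growth_rate=growth_rate(s),
        consumption_yield=max(0.0, consumption),
        excretion_yield=excretion,
        r_squared={"substrate": s_r2, "acetate": a_r2},
    )


def carbon_utilization(y: YieldEstimate) -> float:
    """Carbon utilization rate (mM-C/OD600/h): (consumption - excretion) x growth rate."""
    diff = y.consumption_yield - y.excretion_yield
    if diff < 0:
        raise ValueError("net excretion exceeds carbon intake")
    return diff * y.growth_rate


def maintenance_line(points: Sequence[Tuple[float, float]]) -> MaintenanceLine:
    """OLS line of carbon utilization rate against growth rate.

    The slope (mM-C/OD600) carries the growth-associated carbon cost; the
    y-intercept (mM-C/OD600/h) is the maintenance carbon spend at zero
    growth.  A negative intercept is reported with a warning, not clamped.
    """
    grs = [p[0] for p in points]
    if len(set(grs)) < 2:
        raise ValueError("need at least 2 distinct growth rates")
    slope, intercept, _ = _ols(np.asarray(grs), np.asarray([p[1] for p in points]))
    if intercept < 0:
        warnings.warn(f"negative maintenance intercept {intercept:.4g}; check the data")
    return MaintenanceLine(slope=slope, intercept=intercept)


def ngam_from_intercept(
    model: MetabolicModel,
    line: MaintenanceLine,
    cdw_conv: float,
    substrate: str,
    substrate_carbons: int,
    biomass_id: str = "BIOMASS",
    atpm_id: str = "ATPM",
    closed_exchanges: Sequence[str] = (),
) -> float:
    """Maximal ATP-hydrolysis flux sustained by the zero-growth carbon influx.

    The line's intercept (mM-C/OD600/h) is converted to a substrate uptake
    flux intercept/(cdw_conv * n_C) in mmol/gCDW/h, pinned on the substrate
    exchange, biomass flux is fixed to zero, and flux through the ATP
    hydrolysis reaction is maximized.  The optimum is the NGAM, to be
    installed as that reaction's lower bound.
    """
    if line.intercept <= 0:
        return 0.0
    uptake = line.intercept / (cdw_conv * substrate_carbons)
    bounds: Dict[str, Tuple[float, float]] = {substrate: (-uptake, -uptake)}
    # other carbon sources must not feed the ATP maximization
    for ex in closed_exchanges:
        if ex != substrate:
            ub = model.reaction(ex).upper_bound
            bounds[ex] = (0.0, ub)
    m = set_medium(model.copy(), bounds)
    bio = m.reaction(biomass_id)
    bio.lower_bound = bio.upper_bound = 0.0
    if not m.has_reaction(atpm_id):
        raise ModelError(f"model has no ATP-hydrolysis reaction {atpm_id!r}")
    atpm = m.reaction(atpm_id)
    atpm.lower_bound = 0.0  # maximizing it; any previous NGAM floor is moot
    m.objective_id = atpm_id
    m.objective_sense = "maximize"
    sol = fba(m)
    if sol.status is not FluxStatus.OPTIMAL:
        raise ModelError(
            f"NGAM solve {sol.status.value} with uptake pinned at {uptake:.4g} on {substrate!r}"
        )
    return sol.objective_value


def set_gam(
    model: MetabolicModel,
    gam: float,
    biomass_id: str = "BIOMASS",
    energy_ids: Optional[Mapping[str, str]] = None,
    base_atp: float = 0.0,
) -> MetabolicModel:
    """Copy of ``model`` with the biomass reaction's GAM term set to ``gam``.

    ``base_atp`` is any polymerization ATP demand the biomass reaction
    carries independently of maintenance (zero for the toy network).
    """
    from .composition import DEFAULT_ENERGY_IDS

    eids = dict(DEFAULT_ENERGY_IDS)
    if energy_ids:
        eids.update(energy_ids)
    if gam < 0:
        raise ValueError("GAM must be nonnegative")
    m = model.copy()
    bio = m.reaction(biomass_id)
    total = base_atp + gam
    for key, sign in (("atp", -1), ("h2o", -1), ("adp", 1), ("pi", 1), ("h", 1)):
        mid = eids[key]
        if mid in bio.stoichiometry or total != 0:
            bio.stoichiometry[mid] = sign * total
    return m


def fit_gam(
    model: MetabolicModel,
    observations: Sequence[Tuple[Mapping[str, Tuple[float, float]], float]],
    search_interval: Tuple[float, float] = (0.0, 200.0),
    biomass_id: str = "BIOMASS",
    energy_ids: Optional[Mapping[str, str]] = None,
    base_atp: float = 0.0,
    tol: float = 0.01,
    cdw_conversion: float = float("nan"),
) -> MaintenanceParams:
    """Bisect the GAM so FBA-predicted growth rates match observed ones.

    Each observation is (medium exchange bounds, observed growth rate); the
    bounds pin the measured substrate uptake and acetate secretion fluxes.
    FBA-predicted growth is monotone nonincreasing in GAM (checked), so the
    signed sum of residuals mu_FBA - mu_obs has a single root, found by
    bisection to an interval width below ``tol`` mmol/gCDW.
    """

    def residuals(g: float) -> List[float]:
        mg = set_gam(model, g, biomass_id, energy_ids, base_atp)
        out = []
        for bounds, mu_obs in observations:
            sol = fba(set_medium(mg, bounds))
            if sol.status is not FluxStatus.OPTIMAL:
                raise ModelError(f"infeasible at GAM={g:.4g} for observation mu_obs={mu_obs}")
            out.append(sol.objective_value - mu_obs)
        return out

    lo, hi = search_interval
    h_lo, h_hi = sum(residuals(lo)), sum(residuals(hi))
    h_mid = sum(residuals(0.5 * (lo + hi)))
    if not (h_lo >= h_mid >= h_hi):
        raise ModelError(
            "growth response not monotone nonincreasing in GAM: "
            f"h({lo})={h_lo:.4g}, h(mid)={h_mid:.4g}, h({hi})={h_hi:.4g}"
        )
    if not (h_lo > 0 > h_hi):
        raise ModelError(
            f"no sign change on [{lo}, {hi}]: h({lo})={h_lo:.4g}, h({hi})={h_hi:.4g}; "
            "the interval excludes the fitted GAM"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if sum(residuals(mid)) > 0:
            lo = mid
        else:
            hi = mid
    g_hat = 0.5 * (lo + hi)
    ngam = model.reaction("ATPM").lower_bound if model.has_reaction("ATPM") else 0.0
    return MaintenanceParams(
        ngam=max(0.0, ngam),
        gam=g_hat,
        cdw_conversion=cdw_conversion,
        residuals=tuple(residuals(g_hat)),
    )


@dataclass(frozen=True)
class SubstrateInfo:
    """Exchange-reaction wiring for one batch medium."""

    exchange_id: str
    carbons: int


def estimate_maintenance(
    model: MetabolicModel,
    series: Sequence[BatchSeries],
    cdw_conv: float,
    substrate_info: Mapping[str, SubstrateInfo],
    acetate_exchange: str = "EX_ac",
    biomass_id: str = "BIOMASS",
    atpm_id: str = "ATPM",
    search_interval: Tuple[float, float] = (0.0, 200.0),
) -> MaintenanceParams:
    """Full pipeline: batch series -> yields -> line -> NGAM -> GAM.

    ``substrate_info`` maps each series' medium_label to its substrate
    exchange reaction and carbon count.  The NGAM is installed as the ATP
    hydrolysis reaction's lower bound before the GAM is fitted; during the
    GAM fit each observation pins the measured substrate uptake and acetate
    secretion fluxes.
    """
    points: List[Tuple[float, float]] = []
    obs: List[Tuple[Dict[str, Tuple[float, float]], float]] = []
    for s in series:
        info = substrate_info[s.medium_label]
        y = yields(s)
        points.append((y.growth_rate, carbon_utilization(y)))
        uptake = y.consumption_yield * y.growth_rate / (cdw_conv * info.carbons)
        secretion = y.excretion_yield * y.growth_rate / (cdw_conv * ACETATE_CARBONS)
        bounds = {info.exchange_id: (-uptake, -uptake), acetate_exchange: (secretion, secretion)}
        for other in substrate_info.values():
            if other.exchange_id != info.exchange_id:
                bounds[other.exchange_id] = (0.0, model.reaction(other.exchange_id).upper_bound)
        obs.append((bounds, y.growth_rate))
    line = maintenance_line(points)
    first = substrate_info[series[0].medium_label]
    ngam = ngam_from_intercept(
        model, line, cdw_conv, first.exchange_id, first.carbons,
        biomass_id=biomass_id, atpm_id=atpm_id,
        closed_exchanges=[i.exchange_id for i in substrate_info.values()],
    )
    m = model.copy()
    m.reaction(atpm_id).lower_bound = ngam
    params = fit_gam(
        m, obs, search_interval=search_interval, biomass_id=biomass_id,
        cdw_conversion=cdw_conv,
    )
    return MaintenanceParams(
        ngam=ngam, gam=params.gam, cdw_conversion=cdw_conv, residuals=params.residuals
    )
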