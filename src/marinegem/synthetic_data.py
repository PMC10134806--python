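"""Generators for every input the curation pipeline consumes.

The centerpiece is a small three-compartment toy network with known
energetics: substrate uptake (outer-membrane diffusion plus an
inner-membrane transporter), lumped catabolism to a one-carbon precursor
pool, respiration at a fixed 2 ATP per carbon with a finite capacity,
an acetate-overflow branch (partial oxidation: three precursor carbons
yield one two-carbon acetate, one CO2 and 2 ATP), a parameterized biomass
reaction and an ATP-hydrolysis maintenance reaction.  Overflow is not
prescribed — it emerges from FBA whenever the respiration capacity
saturates, which happens on the fast substrate but not the slow one,
mirroring overflow metabolism in batch culture.  Because every ATP is made
at the same 2 ATP per carbon burned, the carbon-utilization-versus-growth
line implied by the network is exactly linear, so the slope/intercept route
to GAM and NGAM is exact on noiseless data.

Batch time series, composition measurements, pellet weighings and plate
curves are generated from stated forward models with seeded Gaussian noise:
multiplicative on OD (how turbidity errors behave), additive on
concentrations and weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cdw import AddBackSeries
from .composition import (
    GrowthRateFits,
    OsmolyteSpec,
    ReferenceRemainder,
    composition_at,
    reference_remainder,
)
from .gapfill_phenotype import PlateCurve
from .maintenance import BatchSeries
from .model_core import (
    Compartment,
    FluxStatus,
    Metabolite,
    MetabolicModel,
    ModelError,
    Reaction,
    fba,
)

__all__ = [
    "SubstrateSpec",
    "ToyNetworkSpec",
    "SimConfig",
    "make_toy_model",
    "simulate_batch",
    "simulate_composition",
    "simulate_pellets",
    "simulate_plate",
    "toy_biomass_builder",
    "TOY_RESP_ATP_PER_CARBON",
    "TOY_CARBON_PER_GCDW",
]

#: ATP produced per precursor carbon respired (and per carbon burned in overflow).
TOY_RESP_ATP_PER_CARBON = 2.0
#: Precursor carbons consumed per gCDW by the toy biomass reaction (mmol/gCDW).
TOY_CARBON_PER_GCDW = 40.0

#: Approximate carbon mass fraction (gC/g) per biomass component, used to turn
#: a growth-rate-dependent composition into the toy precursor demand.
COMPONENT_CARBON_FRACTION = {
    "protein": 0.53,
    "rna": 0.34,
    "glutamate": 0.41,
    "glutamine": 0.41,
    "DNA": 0.36,
    "LPS": 0.40,
    "lipid": 0.65,
    "murein": 0.45,
    "inorganic_ions": 0.0,
    "soluble_pool": 0.40,
}
CARBON_MOLAR_MASS = 12.011


@dataclass(frozen=True)
class SubstrateSpec:
    name: str
    carbons: int
    atp_yield: float  # total ATP per molecule fully respired
    uptake_cap: float  # mmol/gCDW/h

    def __post_init__(self) -> None:
        if self.atp_yield <= 0 or self.uptake_cap <= 0 or self.carbons < 1:
            raise ValueError("substrate parameters must be positive")


@dataclass(frozen=True)
class ToyNetworkSpec:
    """Parameters of the shared toy network.

    Defaults: a fast 6-carbon substrate (glucose-like, uptake cap 10) that
    saturates respiration and overflows acetate, a slow one (galactose-like,
    cap 2) that does not, GAM 20 mmol ATP/gCDW and NGAM 5 mmol ATP/gCDW/h.
    """

    substrates: Tuple[SubstrateSpec, ...] = (
        SubstrateSpec("glc", 6, 12.0, 10.0),
        SubstrateSpec("gal", 6, 12.0, 2.0),
    )
    respiration_cap: float = 10.0  # mmol C/gCDW/h through respiration
    carbon_per_gcdw: float = TOY_CARBON_PER_GCDW
    gam: float = 20.0  # mmol ATP/gCDW
    ngam: float = 5.0  # mmol ATP/gCDW/h

    def __post_init__(self) -> None:
        if not self.substrates:
            raise ValueError("need at least one substrate")
        if self.respiration_cap <= 0 or self.carbon_per_gcdw <= 0:
            raise ValueError("respiration_cap and carbon_per_gcdw must be positive")
        if self.gam < 0 or self.ngam < 0:
            raise ValueError("GAM and NGAM must be nonnegative")
        for s in self.substrates:
            if s.atp_yield < TOY_RESP_ATP_PER_CARBON * s.carbons:
                raise ValueError(
                    f"substrate {s.name!r}: atp_yield below full respiration "
                    f"({TOY_RESP_ATP_PER_CARBON * s.carbons}); inconsistent spec"
                )

    def substrate(self, name: str) -> SubstrateSpec:
        for s in self.substrates:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class SimConfig:
    seed: int
    od0: float = 0.02
    sample_times: Optional[Tuple[float, ...]] = None
    #: channel -> sd; "od" and "plate" are relative, "substrate"/"acetate" are
    #: relative to the channel's total change, "composition" is absolute
    #: mg/(OD600·mL).
    noise: Mapping[str, float] = field(
        default_factory=lambda: {
            "od": 0.01, "substrate": 0.01, "acetate": 0.01,
            "composition": 0.01, "plate": 0.02,
        }
    )
    cdw_conv: float = 0.5  # mg CDW per OD600·mL

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.noise.values()):
            raise ValueError("noise sds must be nonnegative")
        if self.od0 <= 0 or self.cdw_conv <= 0:
            raise ValueError("od0 and cdw_conv must be positive")


BIG = 1000.0


def make_toy_model(spec: ToyNetworkSpec = ToyNetworkSpec()) -> MetabolicModel:
    """Build the toy metabolic model for ``spec`` (FBA-feasible on each substrate)."""
    C, P, E = Compartment.CYTOPLASM, Compartment.PERIPLASM, Compartment.EXTRACELLULAR
    mets = [
        Metabolite("prec_c", C, name="precursor carbon"),
        Metabolite("atp_c", C), Metabolite("adp_c", C), Metabolite("pi_c", C),
        Metabolite("h2o_c", C), Metabolite("h_c", C), Metabolite("co2_c", C),
        Metabolite("ac_c", C), Metabolite("ac_p", P), Metabolite("ac_e", E),
        Metabolite("co2_e", E), Metabolite("h2o_e", E), Metabolite("h_e", E),
    ]
    rxns: List[Reaction] = []
    for s in spec.substrates:
        mets += [
            Metabolite(f"{s.name}_e", E), Metabolite(f"{s.name}_p", P),
            Metabolite(f"{s.name}_c", C),
        ]
        rxns.append(Reaction(f"EX_{s.name}", {f"{s.name}_e": -1.0}, -s.uptake_cap, BIG))
        rxns.append(Reaction(f"DF_{s.name}_ep", {f"{s.name}_e": -1.0, f"{s.name}_p": 1.0}, -BIG, BIG))
        rxns.append(Reaction(f"T_{s.name}_pc", {f"{s.name}_p": -1.0, f"{s.name}_c": 1.0}, 0.0, BIG))
        direct_atp = s.atp_yield - TOY_RESP_ATP_PER_CARBON * s.carbons
        stoich = {f"{s.name}_c": -1.0, "prec_c": float(s.carbons)}
        if direct_atp > 0:
            stoich.update({
                "adp_c": -direct_atp, "pi_c": -direct_atp,
                "atp_c": direct_atp, "h2o_c": direct_atp,
            })
        rxns.append(Reaction(f"CAT_{s.name}", stoich, 0.0, BIG))
    eps = TOY_RESP_ATP_PER_CARBON
    rxns += [
        Reaction("RESP", {
            "prec_c": -1.0, "adp_c": -eps, "pi_c": -eps,
            "co2_c": 1.0, "atp_c": eps, "h2o_c": eps,
        }, 0.0, spec.respiration_cap),
        # partial oxidation: 3 precursor carbons -> acetate (2C) + CO2, at the
        # same 2 ATP per carbon burned as respiration
        Reaction("OVR", {
            "prec_c": -3.0, "adp_c": -eps, "pi_c": -eps,
            "ac_c": 1.0, "co2_c": 1.0, "atp_c": eps, "h2o_c": eps,
        }, 0.0, BIG),
        # uncoupled oxidation (energy spilling): burns carbon without ATP gain;
        # idle at any growth optimum but lets pinned-flux fits shed excess carbon
        Reaction("FOX", {"prec_c": -1.0, "co2_c": 1.0}, 0.0, BIG),
        Reaction("T_ac_cp", {"ac_c": -1.0, "ac_p": 1.0}, -BIG, BIG),
        Reaction("DF_ac_pe", {"ac_p": -1.0, "ac_e": 1.0}, -BIG, BIG),
        Reaction("EX_ac", {"ac_e": -1.0}, 0.0, BIG),
        Reaction("T_co2", {"co2_c": -1.0, "co2_e": 1.0}, 0.0, BIG),
        Reaction("EX_co2", {"co2_e": -1.0}, 0.0, BIG),
        Reaction("T_h2o", {"h2o_c": -1.0, "h2o_e": 1.0}, -BIG, BIG),
        Reaction("EX_h2o", {"h2o_e": -1.0}, -BIG, BIG),
        Reaction("T_h", {"h_c": -1.0, "h_e": 1.0}, -BIG, BIG),
        Reaction("EX_h", {"h_e": -1.0}, -BIG, BIG),
        Reaction("ATPM", {
            "atp_c": -1.0, "h2o_c": -1.0, "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0,
        }, spec.ngam, BIG),
        Reaction("BIOMASS", {
            "prec_c": -spec.carbon_per_gcdw,
            "atp_c": -spec.gam, "h2o_c": -spec.gam,
            "adp_c": spec.gam, "pi_c": spec.gam, "h_c": spec.gam,
        }, 0.0, BIG),
    ]
    model = MetabolicModel(mets, rxns, objective_id="BIOMASS", objective_sense="maximize")
    for s in spec.substrates:
        sol = fba(_only_substrate(model, spec, s.name))
        if sol.status is not FluxStatus.OPTIMAL:
            raise ModelError(f"toy model infeasible on {s.name!r}: inconsistent spec")
    return model


def _only_substrate(model: MetabolicModel, spec: ToyNetworkSpec, name: str) -> MetabolicModel:
    """Close every substrate exchange except ``name``."""
    m = model.copy()
    for s in spec.substrates:
        ex = m.reaction(f"EX_{s.name}")
        ex.lower_bound = -s.uptake_cap if s.name == name else 0.0
    return m


def toy_steady_state(spec: ToyNetworkSpec, substrate: str) -> Dict[str, float]:
    """FBA fluxes of the toy model growing on one substrate (others closed)."""
    model = make_toy_model(spec)
    sol = fba(_only_substrate(model, spec, substrate))
    if sol.status is not FluxStatus.OPTIMAL:
        raise ModelError(f"toy model does not grow on {substrate!r}")
    return sol.fluxes


def simulate_batch(
    spec: ToyNetworkSpec,
    substrate: str,
    cfg: SimConfig,
    substrate_mM0: Optional[float] = None,
) -> BatchSeries:
    """Exponential batch culture of the toy model on one substrate.

    OD grows as od0*exp(mu*t) with mu from FBA; substrate and acetate follow
    the FBA yields linearly in OD (concentration change per OD equals
    flux * cdw_conv / mu).  Seeded Gaussian noise: multiplicative on OD,
    additive on concentrations scaled to each channel's total change.
    """
    sub = spec.substrate(substrate)
    fluxes = toy_steady_state(spec, substrate)
    mu = fluxes["BIOMASS"]
    if mu <= 0:
        raise ModelError(f"no growth on {substrate!r}; cannot simulate batch")
    uptake = -fluxes[f"EX_{substrate}"]
    secretion = max(0.0, fluxes["EX_ac"])
    y_sub = uptake * cfg.cdw_conv / mu  # mM per OD600
    y_ace = secretion * cfg.cdw_conv / mu

    times = cfg.sample_times
    if times is None:
        t_end = math.log(0.5 / cfg.od0) / mu
        times = tuple(np.linspace(0.0, t_end, 8))
    times = np.asarray(times, dtype=float)
    od_true = cfg.od0 * np.exp(mu * times)
    d_od = od_true - cfg.od0
    if substrate_mM0 is None:
        substrate_mM0 = 1.1 * y_sub * d_od[-1]
    sub_true = substrate_mM0 - y_sub * d_od
    ace_true = y_ace * d_od
    if sub_true[-1] < 0:
        keep = sub_true >= 0
        warnings.warn(f"substrate exhausted before the last sample; truncating to {keep.sum()} points")
        times, od_true, sub_true, ace_true = (a[keep] for a in (times, od_true, sub_true, ace_true))

    rng = np.random.default_rng(cfg.seed)
    od = od_true * (1.0 + rng.normal(0.0, cfg.noise.get("od", 0.0), od_true.shape))
    sub_sd = cfg.noise.get("substrate", 0.0) * (y_sub * d_od[-1] if d_od[-1] > 0 else 1.0)
    ace_scale = ace_true[-1] if ace_true[-1] > 0 else 0.0
    ace_sd = cfg.noise.get("acetate", 0.0) * ace_scale
    sub_obs = sub_true + rng.normal(0.0, sub_sd, sub_true.shape) if sub_sd > 0 else sub_true
    ace_obs = ace_true + rng.normal(0.0, ace_sd, ace_true.shape) if ace_sd > 0 else ace_true
    return BatchSeries(
        times=tuple(times),
        od=tuple(np.maximum(od, 1e-6)),
        substrate_mM=tuple(np.maximum(sub_obs, 0.0)),
        acetate_mM=tuple(ace_obs if ace_scale > 0 else np.zeros_like(ace_true)),
        substrate_carbons=sub.carbons,
        medium_label=substrate,
    )


def simulate_composition(
    fits: GrowthRateFits,
    gr_values: Sequence[float],
    replicates: int,
    cfg: SimConfig,
) -> pd.DataFrame:
    """RNA/protein/CDW per OD600·mL at each growth rate, with Gaussian noise.

    Columns: growth_rate, replicate, rna, protein, cdw (mg/(OD600·mL)).
    Negative draws are resampled (bounded retries) since contents are masses.
    """
    for gr in gr_values:
        if not (0 <= gr <= fits.gr_max):
            raise ValueError(f"growth rate {gr} outside fit range")
    rng = np.random.default_rng(cfg.seed)
    sd = cfg.noise.get("composition", 0.0)
    rows = []
    for gr in gr_values:
        for rep in range(replicates):
            row = {"growth_rate": gr, "replicate": rep}
            for channel in ("rna", "protein", "cdw"):
                mean = getattr(fits, channel)(gr)
                for _ in range(100):
                    val = mean + rng.normal(0.0, sd) if sd > 0 else mean
                    if val > 0:
                        break
                else:
                    raise RuntimeError(f"could not draw positive {channel} at gr={gr}")
                row[channel] = val
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_pellets(
    alpha: float,
    beta: float,
    rho: float,
    w: float,
    z_values: Sequence[float],
) -> AddBackSeries:
    """Exact forward model of pellet weighings for given extracellular water z.

    x = alpha*w + rho*z (dry solids incl. residual salt) and
    y = x + beta*alpha*w + z (adds cellular and extracellular water).
    """
    if alpha <= 0 or beta < 0 or w <= 0 or not (0 <= rho < 1):
        raise ValueError("invalid pellet parameters")
    if rho * beta >= 1:
        raise ValueError("rho * beta must be < 1")
    pellets = []
    for z in z_values:
        if z < 0:
            raise ValueError("z must be nonnegative")
        x = alpha * w + rho * z
        y = x + beta * alpha * w + z
        pellets.append((x, y))
    return AddBackSeries(pellets=tuple(pellets), w=w, beta=beta)


def simulate_plate(
    truth: Mapping[str, bool],
    cfg: SimConfig,
    read_interval_h: float = 12.0,
    total_h: float = 240.0,
) -> List[PlateCurve]:
    """Plate-reader curves: growers cross the call threshold well before 20 h.

    Growers follow a logistic curve saturating at OD 1.2; non-growers drift
    below OD 0.3.  Multiplicative seeded noise per reading.
    """
    if not truth:
        raise ValueError("truth map must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    times = np.arange(0.0, total_h + 1e-9, read_interval_h)
    sd = cfg.noise.get("plate", 0.0)
    curves = []
    for substrate in sorted(truth):
        if truth[substrate]:
            od = 1.2 / (1.0 + np.exp(-0.6 * (times - 10.0)))
        else:
            od = 0.05 + 0.1 * (1.0 - np.exp(-times / 50.0))
        if sd > 0:
            od = od * (1.0 + rng.normal(0.0, sd, od.shape))
        curves.append(PlateCurve(
            substrate=substrate, times=tuple(times),
            od=tuple(np.maximum(od, 0.0)), replicate=0,
        ))
    return curves


def toy_biomass_builder(
    spec: ToyNetworkSpec,
    fits: GrowthRateFits,
    osmo: OsmolyteSpec = OsmolyteSpec(),
    remainder: Optional[ReferenceRemainder] = None,
) -> Callable[[float], Reaction]:
    """Growth-rate-dependent biomass reaction for the toy network.

    The composition at a growth rate is condensed to its total carbon
    content (per-component carbon fractions), giving the precursor demand
    in mmol C/gCDW; the GAM term is kept from ``spec``.  At the reference
    composition this reproduces the toy default of ~40 mmol C/gCDW.
    """
    if remainder is None:
        remainder = reference_remainder()

    def build(gr: float) -> Reaction:
        comp = composition_at(min(gr, fits.gr_max), fits, osmo, remainder)
        carbon_g = sum(
            f * COMPONENT_CARBON_FRACTION.get(name, 0.4)
            for name, f in comp.fractions.items()
        )
        prec = 1000.0 * carbon_g / CARBON_MOLAR_MASS
        return Reaction("BIOMASS", {
            "prec_c": -prec,
            "atp_c": -spec.gam, "h2o_c": -spec.gam,
            "adp_c": spec.gam, "pi_c": spec.gam, "h_c": spec.gam,
        }, 0.0, BIG)

    return build
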