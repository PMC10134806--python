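"""Parsimonious gap-filling and growth-phenotype comparison.

Draft metabolic models inherit the gaps of genome annotation, so pathways
are completed against observed growth: if the organism grows on a carbon
source but the model cannot, the smallest set of candidate reactions from a
universal database that restores biomass flux is added.  Minimality is
certified by a mixed-integer program (binary indicator per candidate,
big-M-coupled to its flux, minimized subject to steady state, bounds and a
biomass floor).

Plate-reader curves give the in vivo growth call: an OD600 increase of at
least 0.9 within 20 h of inoculation.  In silico calls are made under three
transport assumptions — existing transporters only, free diffusion into the
periplasm, or free diffusion all the way into the cytoplasm — because
missing transporter annotation (or expression) is a dominant source of
in vivo/in silico disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import lil_matrix

from .model_core import (
    Compartment,
    FluxStatus,
    Metabolite,
    MetabolicModel,
    ModelError,
    Reaction,
    fba,
    set_medium,
)

__all__ = [
    "PlateCurve",
    "UniversalDB",
    "GapfillResult",
    "TransportMode",
    "PhenotypeRecord",
    "call_growth",
    "gapfill",
    "phenotype_compare",
    "GROWTH_DELTA_OD",
    "GROWTH_WINDOW_H",
    "MIN_BIOMASS_FLUX",
]

#: In vivo growth call: OD600 increase required within the time window.
GROWTH_DELTA_OD = 0.9
GROWTH_WINDOW_H = 20.0
#: In silico growth call: minimal biomass flux (1/h) counted as growth.
MIN_BIOMASS_FLUX = 1e-6
BIG_M = 1000.0


@dataclass(frozen=True)
class PlateCurve:
    substrate: str
    times: Tuple[float, ...]  # h
    od: Tuple[float, ...]
    replicate: int = 0

    def __post_init__(self) -> None:
        if len(self.times) != len(self.od):
            raise ValueError("times and od must have the same length")
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("times must be increasing")
        if any(o < 0 for o in self.od):
            raise ValueError("OD must be nonnegative")


@dataclass(frozen=True)
class UniversalDB:
    """Candidate reactions (with any new metabolites they need) for gap-filling."""

    reactions: Tuple[Reaction, ...]
    metabolites: Tuple[Metabolite, ...] = ()
    source_tags: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class GapfillResult:
    added: Tuple[str, ...]
    achieved_biomass_flux: float
    optimal: bool  # minimality proven by the MILP


class TransportMode(str, Enum):
    TRANSPORTER_REQUIRED = "transporter_required"
    FREE_DIFFUSION_PERIPLASM = "free_diffusion_periplasm"
    FREE_DIFFUSION_CYTOPLASM = "free_diffusion_cytoplasm"


@dataclass(frozen=True)
class PhenotypeRecord:
    substrate: str
    in_vivo: bool
    in_silico: Mapping[str, bool]
    error: Optional[str] = None


def call_growth(curve: PlateCurve) -> bool:
    """In vivo growth call from a plate curve.

    True iff the OD600 increase over the initial reading reaches
    ``GROWTH_DELTA_OD`` at some time up to ``GROWTH_WINDOW_H`` hours, with
    linear interpolation between readings (plates are read about daily, so
    the 20-h point is rarely sampled exactly).  The threshold is inclusive.
    """
    if len(curve.times) < 2:
        raise ValueError("need at least two readings")
    t = np.asarray(curve.times, dtype=float)
    od = np.asarray(curve.od, dtype=float)
    if t[-1] < GROWTH_WINDOW_H:
        raise ValueError(f"curve spans only {t[-1]} h; need >= {GROWTH_WINDOW_H} h")
    mask = t <= GROWTH_WINDOW_H
    candidates = list(od[mask])
    candidates.append(float(np.interp(GROWTH_WINDOW_H, t, od)))
    return bool(max(candidates) - od[0] >= GROWTH_DELTA_OD)


# ---------------------------------------------------------------------------
# Gap-filling MILP
# ---------------------------------------------------------------------------

def gapfill(
    model: MetabolicModel,
    db: UniversalDB,
    medium: Mapping[str, Tuple[float, float]],
    min_biomass: float = MIN_BIOMASS_FLUX,
    big_m: float = BIG_M,
    time_limit: Optional[float] = None,
) -> GapfillResult:
    """Add a provably minimum-cardinality reaction set enabling biomass flux.

    Solves  min sum_j y_j  s.t.  S v = 0, bounds, |v_j| <= M y_j for each
    candidate j, v_biomass >= min_biomass, y binary.  Ties between equally
    small sets are broken toward lexicographically smaller reaction ids via
    infinitesimal objective weights.  If the incumbent at a solver time
    limit is feasible but unproven, it is returned with ``optimal=False``.
    """
    model_ids = {r.id for r in model.reactions}
    cand_ids = [r.id for r in db.reactions]
    if model_ids & set(cand_ids):
        raise ModelError(f"candidate ids overlap the model: {sorted(model_ids & set(cand_ids))}")

    base = set_medium(model, medium)
    sol = fba(base)
    if sol.status is FluxStatus.OPTIMAL and sol.objective_value >= min_biomass:
        return GapfillResult(added=(), achieved_biomass_flux=sol.objective_value, optimal=True)

    # assemble the extended network
    mets = list(base.metabolites)
    known = {m.id for m in mets}
    for m in db.metabolites:
        if m.id not in known:
            mets.append(m)
            known.add(m.id)
    reactions = list(base.reactions) + [r for r in db.reactions]
    ext = MetabolicModel(
        metabolites=mets, reactions=reactions,
        objective_id=base.objective_id, objective_sense="maximize",
    )
    S, _, rxn_ids = ext.stoichiometric_matrix()
    n = len(rxn_ids)
    k = len(cand_ids)
    cand_pos = {rid: j for j, rid in enumerate(rxn_ids) if rid in set(cand_ids)}

    lb = np.array([r.lower_bound for r in ext.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in ext.reactions], dtype=float)
    for rid, j in cand_pos.items():
        lb[j] = max(lb[j], -big_m)
        ub[j] = min(ub[j], big_m)
    j_bio = rxn_ids.index(ext.objective_id)
    # The MILP floor must keep v/M far above the solver's integrality
    # tolerance (~1e-6), or an indicator can sit at y = v/M, be accepted as
    # "integer 0", and silently drop a needed reaction while corrupting the
    # cardinality proof.  Flux polytopes scale from the origin, so any
    # completion that carries the user threshold also carries this floor
    # unless candidate upper bounds bind below it.
    milp_floor = max(min_biomass, 0.1)
    lb[j_bio] = max(lb[j_bio], milp_floor)

    # variables: v (n) then y (k, ordered by sorted candidate id)
    y_order = sorted(cand_ids)
    nvar = n + k
    var_lb = np.concatenate([lb, np.zeros(k)])
    var_ub = np.concatenate([ub, np.ones(k)])
    integrality = np.concatenate([np.zeros(n), np.ones(k)])

    A_eq = np.hstack([S, np.zeros((S.shape[0], k))])
    constraints = [LinearConstraint(A_eq, 0.0, 0.0)]

    # |v_j| <= M y_j, rows: v_j - M y <= 0 and -v_j - M y <= 0
    A_ub = lil_matrix((2 * k, nvar))
    for i, rid in enumerate(y_order):
        j = cand_pos[rid]
        A_ub[2 * i, j] = 1.0
        A_ub[2 * i, n + i] = -big_m
        A_ub[2 * i + 1, j] = -1.0
        A_ub[2 * i + 1, n + i] = -big_m
    if k:
        constraints.append(LinearConstraint(A_ub.toarray(), -np.inf, 0.0))

    delta = 1.0 / (2.0 * max(k, 1) ** 2)
    c = np.zeros(nvar)
    for i in range(k):
        c[n + i] = 1.0 + delta * i / max(k, 1)

    options = {}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = milp(
        c, constraints=constraints, integrality=integrality,
        bounds=Bounds(var_lb, var_ub), options=options,
    )
    if res.status == 2 or (res.x is None and res.status != 0):
        raise ModelError("unfillable gap: no candidate subset restores biomass flux")
    added = tuple(rid for i, rid in enumerate(y_order) if res.x[n + i] > 0.5)

    # verify with a plain LP on model + chosen reactions
    filled = MetabolicModel(
        metabolites=mets,
        reactions=list(base.reactions) + [r for r in db.reactions if r.id in set(added)],
        objective_id=base.objective_id,
        objective_sense="maximize",
    )
    check = fba(filled)
    if check.status is not FluxStatus.OPTIMAL or check.objective_value < min_biomass * (1 - 1e-6):
        raise ModelError("gap-fill verification failed: chosen set does not restore growth")
    return GapfillResult(
        added=added,
        achieved_biomass_flux=check.objective_value,
        optimal=(res.status == 0),
    )


# ---------------------------------------------------------------------------
# Phenotype comparison under transport modes
# ---------------------------------------------------------------------------

def _with_substrate(
    model: MetabolicModel,
    met_e: str,
    mode: TransportMode,
    uptake_cap: float,
) -> MetabolicModel:
    """Transient exchange (and mode-dependent diffusion reactions) for one substrate."""
    m = model.copy()
    if not m.has_metabolite(met_e):
        m.metabolites.append(Metabolite(id=met_e, compartment=Compartment.EXTRACELLULAR))
    ex_id = f"EX_{met_e}__pheno"
    m.reactions.append(Reaction(id=ex_id, stoichiometry={met_e: -1.0},
                                lower_bound=-uptake_cap, upper_bound=BIG_M))
    stem = met_e[:-2] if met_e.endswith("_e") else met_e
    met_p, met_c = f"{stem}_p", f"{stem}_c"
    if mode in (TransportMode.FREE_DIFFUSION_PERIPLASM, TransportMode.FREE_DIFFUSION_CYTOPLASM):
        if not m.has_metabolite(met_p):
            m.metabolites.append(Metabolite(id=met_p, compartment=Compartment.PERIPLASM))
        m.reactions.append(Reaction(id=f"DF_{stem}_ep__pheno",
                                    stoichiometry={met_e: -1.0, met_p: 1.0},
                                    lower_bound=-BIG_M, upper_bound=BIG_M))
    if mode is TransportMode.FREE_DIFFUSION_CYTOPLASM:
        if not m.has_metabolite(met_c):
            m.metabolites.append(Metabolite(id=met_c, compartment=Compartment.CYTOPLASM))
        m.reactions.append(Reaction(id=f"DF_{stem}_pc__pheno",
                                    stoichiometry={met_p: -1.0, met_c: 1.0},
                                    lower_bound=-BIG_M, upper_bound=BIG_M))
    m.validate()
    return m


def phenotype_compare(
    model: MetabolicModel,
    records: Sequence[Tuple[str, bool]],
    substrate_map: Mapping[str, str],
    medium_base: Mapping[str, Tuple[float, float]],
    modes: Optional[Sequence[TransportMode]] = None,
    uptake_cap: float = 10.0,
    min_biomass: float = MIN_BIOMASS_FLUX,
) -> Tuple[List[PhenotypeRecord], Dict[str, Dict[str, int]]]:
    """In vivo vs in silico growth calls per substrate and transport mode.

    ``records`` holds (substrate name, in vivo grew?); ``substrate_map``
    maps substrate names to extracellular metabolite ids (added transiently
    when absent, and never persisted — permanent exchanges belong only to
    experimentally verified carbon sources).  ``medium_base`` is applied to
    existing exchanges first (typically closing all other carbon sources).
    Diffusion reactions added by the free-diffusion modes are plain
    uncatalyzed transfers: they never phosphorylate or otherwise transform
    the substrate, so substrates whose catabolism needs transporter-coupled
    chemistry still fail without their transporter.

    Returns per-substrate records and, per mode, the tally of the four
    agreement categories.
    """
    if modes is None:
        modes = list(TransportMode)
    base = set_medium(model, medium_base)
    out: List[PhenotypeRecord] = []
    counts = {
        mode.value: {"both": 0, "neither": 0, "in_silico_only": 0, "in_vivo_only": 0}
        for mode in modes
    }
    for substrate, in_vivo in records:
        if substrate not in substrate_map:
            out.append(PhenotypeRecord(substrate, in_vivo, {},
                                       error=f"no metabolite mapping for {substrate!r}"))
            continue
        met_e = substrate_map[substrate]
        in_silico: Dict[str, bool] = {}
        for mode in modes:
            m = _with_substrate(base, met_e, mode, uptake_cap)
            sol = fba(m)
            grew = sol.status is FluxStatus.OPTIMAL and sol.objective_value >= min_biomass
            in_silico[mode.value] = grew
            if grew and in_vivo:
                counts[mode.value]["both"] += 1
            elif grew:
                counts[mode.value]["in_silico_only"] += 1
            elif in_vivo:
                counts[mode.value]["in_vivo_only"] += 1
            else:
                counts[mode.value]["neither"] += 1
        out.append(PhenotypeRecord(substrate, in_vivo, in_silico))
    return out, counts
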