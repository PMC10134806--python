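"""Stoichiometric model representation, SBML I/O, and flux balance analysis.

A metabolic model is a stoichiometric matrix ``S`` over metabolites x reactions,
flux bounds ``v_min <= v <= v_max`` and a linear objective ``c``.  Flux balance
analysis (FBA) solves the linear program

    max (or min)  c' v   s.t.   S v = 0,   v_min <= v <= v_max

Exchange reactions are written as ``metabolite <-> (nothing)`` with uptake as
negative flux; the biomass reaction carries flux in 1/h under the convention
that it consumes one gram of building blocks per gram cell dry weight.  All
other fluxes are in mmol/gCDW/h.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import lil_matrix

__all__ = [
    "Compartment",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxStatus",
    "FluxSolution",
    "ModelStats",
    "ModelError",
    "SBMLFormatError",
    "read_sbml",
    "write_sbml",
    "fba",
    "set_medium",
    "model_stats",
    "DEFAULT_COMPARTMENT_MAP",
]


class ModelError(ValueError):
    """Raised when a model or operation input violates its invariants."""


class SBMLFormatError(ModelError):
    """Raised when an SBML file cannot be interpreted as a flux model."""


class Compartment(str, Enum):
    CYTOPLASM = "cytoplasm"
    PERIPLASM = "periplasm"
    EXTRACELLULAR = "extracellular"


#: SBML compartment id -> Compartment used by :func:`read_sbml`.
DEFAULT_COMPARTMENT_MAP: Dict[str, Compartment] = {
    "c": Compartment.CYTOPLASM,
    "cyt": Compartment.CYTOPLASM,
    "cytoplasm": Compartment.CYTOPLASM,
    "p": Compartment.PERIPLASM,
    "per": Compartment.PERIPLASM,
    "periplasm": Compartment.PERIPLASM,
    "e": Compartment.EXTRACELLULAR,
    "ext": Compartment.EXTRACELLULAR,
    "extracellular": Compartment.EXTRACELLULAR,
}

_SBML_COMPARTMENT_ID = {
    Compartment.CYTOPLASM: "c",
    Compartment.PERIPLASM: "p",
    Compartment.EXTRACELLULAR: "e",
}


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: Compartment
    name: str = ""
    formula: Optional[str] = None
    charge: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("metabolite id must be nonempty")
        if not isinstance(self.compartment, Compartment):
            raise ModelError(f"invalid compartment {self.compartment!r}")


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float
    upper_bound: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("reaction id must be nonempty")
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r}: stoichiometry is empty")
        for met, coef in self.stoichiometry.items():
            if not math.isfinite(coef):
                raise ModelError(f"reaction {self.id!r}: non-finite coefficient for {met!r}")
        if not (self.lower_bound <= self.upper_bound):
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )


class FluxStatus(str, Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"


@dataclass
class FluxSolution:
    status: FluxStatus
    objective_value: float
    fluxes: Dict[str, float]

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


@dataclass
class ModelStats:
    total_reactions: int
    internal_reactions: int
    transport_reactions: int
    exchange_reactions: int
    total_metabolites: int
    intracellular: int
    periplasmic: int
    extracellular: int

    def as_dict(self) -> Dict[str, int]:
        return dict(self.__dict__)


@dataclass
class MetabolicModel:
    metabolites: List[Metabolite]
    reactions: List[Reaction]
    objective_id: str
    objective_sense: str = "maximize"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ModelError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelError("duplicate reaction ids")
        known = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ModelError(f"reaction {r.id!r} references unknown metabolites {sorted(missing)}")
        if self.objective_id not in set(rxn_ids):
            raise ModelError(f"objective reaction {self.objective_id!r} not in model")
        if self.objective_sense not in ("maximize", "minimize"):
            raise ModelError(f"objective_sense must be maximize/minimize, got {self.objective_sense!r}")

    # -- convenience accessors -------------------------------------------------

    def reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise KeyError(reaction_id)

    def metabolite(self, metabolite_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == metabolite_id:
                return m
        raise KeyError(metabolite_id)

    def has_reaction(self, reaction_id: str) -> bool:
        return any(r.id == reaction_id for r in self.reactions)

    def has_metabolite(self, metabolite_id: str) -> bool:
        return any(m.id == metabolite_id for m in self.metabolites)

    def exchange_ids(self) -> List[str]:
        return [r.id for r in self.reactions if len(r.stoichiometry) == 1]

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    def stoichiometric_matrix(self) -> Tuple[np.ndarray, List[str], List[str]]:
        """Dense S (metabolites x reactions) plus row and column id orders."""
        met_ids = [m.id for m in self.metabolites]
        rxn_ids = [r.id for r in self.reactions]
        idx = {mid: i for i, mid in enumerate(met_ids)}
        S = lil_matrix((len(met_ids), len(rxn_ids)))
        for j, r in enumerate(self.reactions):
            for mid, coef in r.stoichiometry.items():
                S[idx[mid], j] = coef
        return S.toarray(), met_ids, rxn_ids


# ---------------------------------------------------------------------------
# Flux balance analysis
# ---------------------------------------------------------------------------

def fba(model: MetabolicModel) -> FluxSolution:
    """Solve the FBA linear program for ``model``.

    Returns a :class:`FluxSolution` whose status is ``infeasible`` or
    ``unbounded`` (not an exception) when the constraint set admits no
    optimum.  When optimal, ``|S v| <= 1e-6`` element-wise and all bounds
    hold to the same tolerance.
    """
    model.validate()
    S, _met_ids, rxn_ids = model.stoichiometric_matrix()
    n = len(rxn_ids)
    c = np.zeros(n)
    j_obj = rxn_ids.index(model.objective_id)
    c[j_obj] = -1.0 if model.objective_sense == "maximize" else 1.0
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    if res.status == 2:
        return FluxSolution(FluxStatus.INFEASIBLE, float("nan"), {})
    if res.status == 3:
        return FluxSolution(FluxStatus.UNBOUNDED, float("inf"), {})
    if res.status != 0:
        raise ModelError(f"LP solver failure: {res.message}")
    fluxes = {rid: float(v) for rid, v in zip(rxn_ids, res.x)}
    obj = fluxes[model.objective_id]
    return FluxSolution(FluxStatus.OPTIMAL, obj, fluxes)


def set_medium(
    model: MetabolicModel,
    exchange_bounds: Mapping[str, Tuple[float, float]],
) -> MetabolicModel:
    """Return a copy of ``model`` with exchange-reaction bounds replaced.

    Uptake is negative flux, so a medium that supplies a substrate at up to
    10 mmol/gCDW/h is ``{"EX_glc": (-10, 1000)}``.  Only exchange reactions
    (touching exactly one metabolite) may be listed.
    """
    exchanges = set(model.exchange_ids())
    new = model.copy()
    for rid, (lb, ub) in exchange_bounds.items():
        if not new.has_reaction(rid):
            raise ModelError(f"unknown exchange reaction {rid!r}")
        if rid not in exchanges:
            raise ModelError(f"reaction {rid!r} is not an exchange reaction")
        if lb > ub:
            raise ModelError(f"exchange {rid!r}: lb {lb} > ub {ub}")
        r = new.reaction(rid)
        r.lower_bound = float(lb)
        r.upper_bound = float(ub)
    return new


def model_stats(model: MetabolicModel) -> ModelStats:
    """Classify reactions and metabolites the way model overview tables do.

    Exchange reactions touch exactly one metabolite; transport reactions are
    non-exchange reactions whose metabolites span at least two compartments;
    the rest are internal.  The exchange/transport split of bidirectional
    diffusion reactions is a convention; only the totals are robust.
    """
    comp_of = {m.id: m.compartment for m in model.metabolites}
    n_ex = n_tr = n_int = 0
    for r in model.reactions:
        if len(r.stoichiometry) == 1:
            n_ex += 1
        elif len({comp_of[mid] for mid in r.stoichiometry}) >= 2:
            n_tr += 1
        else:
            n_int += 1
    n_c = sum(1 for m in model.metabolites if m.compartment is Compartment.CYTOPLASM)
    n_p = sum(1 for m in model.metabolites if m.compartment is Compartment.PERIPLASM)
    n_e = sum(1 for m in model.metabolites if m.compartment is Compartment.EXTRACELLULAR)
    return ModelStats(
        total_reactions=len(model.reactions),
        internal_reactions=n_int,
        transport_reactions=n_tr,
        exchange_reactions=n_ex,
        total_metabolites=len(model.metabolites),
        intracellular=n_c,
        periplasmic=n_p,
        extracellular=n_e,
    )


# ---------------------------------------------------------------------------
# SBML (Level 3 + flux-balance-constraints) input/output
# ---------------------------------------------------------------------------

def read_sbml(
    path: str,
    compartment_map: Optional[Mapping[str, Compartment]] = None,
) -> MetabolicModel:
    """Read an SBML L3+fbc model file.

    Models lacking explicit flux bounds or an active objective are rejected
    rather than silently defaulted.  SBML compartment ids are mapped to the
    three-compartment enum via ``compartment_map``
    (default: c/cyt -> cytoplasm, p/per -> periplasm, e/ext -> extracellular).
    """
    import libsbml

    cmap = dict(DEFAULT_COMPARTMENT_MAP if compartment_map is None else compartment_map)
    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLFormatError(f"SBML parse error in {path}: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLFormatError(f"{path}: no <model> element")
    mplug = sbml_model.getPlugin("fbc")
    if mplug is None:
        raise SBMLFormatError(f"{path}: missing fbc package (flux bounds/objective required)")

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    metabolites = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        comp_id = sp.getCompartment()
        if comp_id not in cmap:
            raise SBMLFormatError(
                f"species {sp.getId()!r}: unmapped compartment {comp_id!r}"
            )
        splug = sp.getPlugin("fbc")
        formula = None
        charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = splug.getCharge()
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=cmap[comp_id],
                formula=formula,
                charge=charge,
            )
        )

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        rplug = rx.getPlugin("fbc")
        if rplug is None or not rplug.isSetLowerFluxBound() or not rplug.isSetUpperFluxBound():
            raise SBMLFormatError(
                f"reaction {rx.getId()!r}: missing fbc flux bounds (no silent defaults)"
            )
        lb_id, ub_id = rplug.getLowerFluxBound(), rplug.getUpperFluxBound()
        if lb_id not in params or ub_id not in params:
            raise SBMLFormatError(
                f"reaction {rx.getId()!r}: bound parameter {lb_id!r}/{ub_id!r} not found"
            )
        stoich: Dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        reactions.append(
            Reaction(
                id=rx.getId(),
                name=rx.getName() or "",
                stoichiometry=stoich,
                lower_bound=params[lb_id],
                upper_bound=params[ub_id],
            )
        )

    obj = mplug.getActiveObjective()
    if obj is None or obj.getNumFluxObjectives() != 1:
        raise SBMLFormatError(f"{path}: expected exactly one active flux objective")
    fobj = obj.getFluxObjective(0)
    sense = "maximize" if obj.getType() == "maximize" else "minimize"
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_id=fobj.getReaction(),
        objective_sense=sense,
    )


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write ``model`` as SBML L3V1 with the fbc (version 2) extension.

    Round-trips through :func:`read_sbml` with identical stoichiometry,
    bounds and objective.
    """
    import libsbml

    model.validate()  # refuse to write an invalid model

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId("model")
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    used_comps = {m.compartment for m in model.metabolites}
    for comp in used_comps:
        c = sm.createCompartment()
        c.setId(_SBML_COMPARTMENT_ID[comp])
        c.setName(comp.value)
        c.setConstant(True)

    for m in model.metabolites:
        if not libsbml.SyntaxChecker.isValidSBMLSId(m.id):
            raise SBMLFormatError(f"metabolite id {m.id!r} is not a valid SBML SId")
        sp = sm.createSpecies()
        sp.setId(m.id)
        if m.name:
            sp.setName(m.name)
        sp.setCompartment(_SBML_COMPARTMENT_ID[m.compartment])
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        splug = sp.getPlugin("fbc")
        if m.formula is not None:
            splug.setChemicalFormula(m.formula)
        if m.charge is not None:
            splug.setCharge(int(m.charge))

    for r in model.reactions:
        if not libsbml.SyntaxChecker.isValidSBMLSId(r.id):
            raise SBMLFormatError(f"reaction id {r.id!r} is not a valid SBML SId")
        for suffix, value in (("lb", r.lower_bound), ("ub", r.upper_bound)):
            p = sm.createParameter()
            p.setId(f"{r.id}_{suffix}")
            p.setValue(float(value))
            p.setConstant(True)
        rx = sm.createReaction()
        rx.setId(r.id)
        if r.name:
            rx.setName(r.name)
        rx.setFast(False)
        rx.setReversible(r.lower_bound < 0)
        for mid, coef in sorted(r.stoichiometry.items()):
            if coef < 0:
                sr = rx.createReactant()
                sr.setStoichiometry(-coef)
            elif coef > 0:
                sr = rx.createProduct()
                sr.setStoichiometry(coef)
            else:
                continue
            sr.setSpecies(mid)
            sr.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(f"{r.id}_lb")
        rplug.setUpperFluxBound(f"{r.id}_ub")

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType(model.objective_sense)
    fo = obj.createFluxObjective()
    fo.setReaction(model.objective_id)
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, path) != 1:
        raise IOError(f"could not write SBML to {path}")
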