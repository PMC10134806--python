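"""Growth-rate-dependent biomass composition and biomass-reaction construction.

The macromolecular composition of an exponentially growing cell shifts with
growth rate: RNA content per OD600·mL rises with growth rate while protein
and total dry weight per OD600·mL fall, each well described by a straight
line over the physiological range.  Dividing the RNA and protein lines by
the dry-weight line yields mass fractions (g per g CDW) at any growth rate;
osmolytes (glutamate, with a minor glutamine pool) are treated as
growth-rate-independent fractions, and the residual mass is filled with the
unquantified components of a reference Gram-negative composition (DNA, LPS,
lipids, murein, inorganic ions, soluble pools), scaled down while keeping
their internal proportions.

Monomer proportions come from the genome: amino-acid frequencies from
translated protein-coding regions, RNA nucleotide frequencies from
rRNA-coding regions (rRNA dominates cellular RNA), and DNA nucleotide
frequencies from the whole genome counted over both strands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .model_core import FluxStatus, MetabolicModel, ModelError, Reaction, fba

__all__ = [
    "LinearFit",
    "GrowthRateFits",
    "OsmolyteSpec",
    "MonomerKind",
    "MonomerProfile",
    "ReferenceRemainder",
    "BiomassComposition",
    "reference_fits",
    "reference_remainder",
    "composition_at",
    "aa_profile_from_genome",
    "nt_profile_from_regions",
    "build_biomass_reaction",
    "biomass_component_groups",
    "sensitivity_scan",
    "AA_RESIDUE_MASSES",
    "RNA_RESIDUE_MASSES",
    "DNA_RESIDUE_MASSES",
]

#: Water released per polymerization bond (g/mol).
WATER_MASS = 18.02

# Average free-monomer masses (g/mol); residues are free mass minus one water.
_AA_FREE_MASSES = {
    "A": 89.09, "R": 174.20, "N": 132.12, "D": 133.10, "C": 121.16,
    "E": 147.13, "Q": 146.15, "G": 75.07, "H": 155.15, "I": 131.17,
    "L": 131.17, "K": 146.19, "M": 149.21, "F": 165.19, "P": 115.13,
    "S": 105.09, "T": 119.12, "W": 204.23, "Y": 181.19, "V": 117.15,
}
AA_RESIDUE_MASSES = {aa: m - WATER_MASS for aa, m in _AA_FREE_MASSES.items()}
RNA_RESIDUE_MASSES = {
    "amp": 347.22 - WATER_MASS,
    "cmp": 323.20 - WATER_MASS,
    "gmp": 363.22 - WATER_MASS,
    "ump": 324.18 - WATER_MASS,
}
DNA_RESIDUE_MASSES = {
    "damp": 331.22 - WATER_MASS,
    "dcmp": 307.20 - WATER_MASS,
    "dgmp": 347.22 - WATER_MASS,
    "dtmp": 322.21 - WATER_MASS,
}

#: Representative molar masses (g/mol) for lumped biomass components that are
#: carried as single pseudo-metabolites rather than monomer pools.
DEFAULT_LUMPED_MASSES = {
    "glutamate": 147.13,
    "glutamine": 146.15,
    "LPS": 1500.0,
    "lipid": 750.0,
    "murein": 1000.0,
    "inorganic_ions": 50.0,
    "soluble_pool": 250.0,
}


@dataclass(frozen=True)
class LinearFit:
    """y = slope * gr + intercept, y in mg/(OD600·mL), gr in 1/h."""

    slope: float
    intercept: float

    def __call__(self, gr: float) -> float:
        return self.slope * gr + self.intercept


@dataclass(frozen=True)
class GrowthRateFits:
    rna: LinearFit
    protein: LinearFit
    cdw: LinearFit
    gr_max: float = 1.38

    def __post_init__(self) -> None:
        for gr in np.linspace(0.0, self.gr_max, 25):
            for name in ("rna", "protein", "cdw"):
                if getattr(self, name)(gr) <= 0:
                    raise ValueError(f"{name} fit nonpositive at gr={gr:.3f}")
            if self.cdw(gr) <= self.rna(gr) + self.protein(gr):
                raise ValueError(f"RNA + protein exceed CDW at gr={gr:.3f}")


def reference_fits() -> GrowthRateFits:
    """Measured linear fits for V. splendidus 1A01 (mg/(OD600·mL) vs 1/h)."""
    return GrowthRateFits(
        rna=LinearFit(0.05, 0.05),
        protein=LinearFit(-0.09, 0.38),
        cdw=LinearFit(-0.13, 0.64),
        gr_max=1.38,
    )


@dataclass(frozen=True)
class OsmolyteSpec:
    """Osmolyte mass fractions (g/gCDW): glutamate dominates, glutamine is minor."""

    glutamate_fraction: float = 0.050
    glutamine_fraction: float = 0.005

    def __post_init__(self) -> None:
        for f in (self.glutamate_fraction, self.glutamine_fraction):
            if not (0 <= f <= 0.2):
                raise ValueError("osmolyte fractions must be in [0, 0.2]")
        if self.glutamine_fraction >= self.glutamate_fraction and self.glutamate_fraction > 0:
            raise ValueError("glutamine fraction must be below glutamate fraction")


class MonomerKind(str, Enum):
    AMINO_ACID = "amino_acid"
    RNA_NUCLEOTIDE = "rna_nucleotide"
    DNA_NUCLEOTIDE = "dna_nucleotide"


@dataclass(frozen=True)
class MonomerProfile:
    kind: MonomerKind
    fractions: Mapping[str, float]
    residue_masses: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"monomer fractions sum to {total}, expected 1")
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("monomer fractions must be nonnegative")
        for m in self.fractions:
            if m not in self.residue_masses or self.residue_masses[m] <= 0:
                raise ValueError(f"missing or nonpositive residue mass for {m!r}")

    def mean_residue_mass(self) -> float:
        return sum(f * self.residue_masses[m] for m, f in self.fractions.items())


#: Unquantified biomass components of the E. coli-like reference composition,
#: as mass fractions of the reference organism's CDW (they sum to 0.20).
_IAF1260_LIKE = {
    "DNA": 0.031,
    "LPS": 0.034,
    "lipid": 0.091,
    "murein": 0.025,
    "inorganic_ions": 0.005,
    "soluble_pool": 0.014,
}


@dataclass(frozen=True)
class ReferenceRemainder:
    components: Mapping[str, float]
    reference_total: float = 0.20

    def __post_init__(self) -> None:
        total = sum(self.components.values())
        if abs(total - self.reference_total) > 1e-9:
            raise ValueError(
                f"remainder components sum to {total}, expected {self.reference_total}"
            )


def reference_remainder() -> ReferenceRemainder:
    """iAF1260-like unquantified-component proportions (20% of reference CDW)."""
    return ReferenceRemainder(dict(_IAF1260_LIKE))


@dataclass(frozen=True)
class BiomassComposition:
    """Mass fractions (g/gCDW) of biomass components at one growth rate."""

    fractions: Mapping[str, float]
    gam: float  # mmol ATP / gCDW
    growth_rate: float  # 1/h

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"biomass fractions sum to {total}, expected 1")
        if any(f < -1e-12 for f in self.fractions.values()):
            raise ValueError("biomass fractions must be nonnegative")
        if self.gam < 0:
            raise ValueError("GAM must be nonnegative")


def composition_at(
    gr: float,
    fits: GrowthRateFits,
    osmo: OsmolyteSpec = OsmolyteSpec(),
    remainder: Optional[ReferenceRemainder] = None,
    gam: float = 0.0,
) -> BiomassComposition:
    """Biomass mass fractions at growth rate ``gr`` (1/h).

    Protein and RNA fractions are the measured per-OD lines divided by the
    CDW-per-OD line; osmolytes are fixed fractions; the remaining mass is
    split among the reference's unquantified components in their reference
    proportions.  The fractions sum to exactly 1.
    """
    if remainder is None:
        remainder = reference_remainder()
    if not (0 <= gr <= fits.gr_max):
        raise ValueError(f"growth rate {gr} outside [0, {fits.gr_max}]")
    cdw = fits.cdw(gr)
    fractions = {
        "protein": fits.protein(gr) / cdw,
        "rna": fits.rna(gr) / cdw,
        "glutamate": osmo.glutamate_fraction,
        "glutamine": osmo.glutamine_fraction,
    }
    residual = 1.0 - sum(fractions.values())
    if residual < 0:
        raise ValueError(
            f"measured components exceed total mass at gr={gr} (residual {residual:.4f})"
        )
    for name, ref_frac in remainder.components.items():
        fractions[name] = residual * ref_frac / remainder.reference_total
    # remove rounding drift so the invariant holds exactly
    fractions["soluble_pool"] += 1.0 - sum(fractions.values())
    return BiomassComposition(fractions=fractions, gam=gam, growth_rate=gr)


# ---------------------------------------------------------------------------
# Genome-derived monomer profiles
# ---------------------------------------------------------------------------

def _load_gff(annotation_path: str):
    import gffutils

    return gffutils.create_db(
        annotation_path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )


def aa_profile_from_genome(genome_path: str, annotation_path: str) -> MonomerProfile:
    """Amino-acid molar fractions from translated protein-coding regions.

    Every CDS feature is extracted (minus-strand features are
    reverse-complemented), translated with the standard code, and the 20
    amino acids tallied across all proteins.  Start methionines count; stop
    codons are excluded; ambiguous translations (X) are skipped with a
    warning.  Frequencies are unweighted by expression, so longer genes
    contribute proportionally more — the usual genome-tally approximation.
    """
    from Bio.Seq import Seq

    db = _load_gff(annotation_path)
    counts: Dict[str, int] = {aa: 0 for aa in AA_RESIDUE_MASSES}
    n_used = 0
    for feat in db.features_of_type("CDS"):
        seq = feat.sequence(genome_path, use_strand=True)
        if len(seq) % 3 != 0:
            warnings.warn(f"CDS {feat.id}: length {len(seq)} not divisible by 3; skipped")
            continue
        protein = str(Seq(seq).translate()).rstrip("*")
        for aa in protein:
            if aa in counts:
                counts[aa] += 1
            elif aa == "*":
                continue  # internal stop: tolerate, exclude
            else:
                warnings.warn(f"CDS {feat.id}: ambiguous residue {aa!r} skipped")
        n_used += 1
    total = sum(counts.values())
    if n_used == 0 or total == 0:
        raise ValueError("no usable CDS features in annotation")
    fractions = {aa: c / total for aa, c in counts.items() if c > 0}
    masses = {aa: AA_RESIDUE_MASSES[aa] for aa in fractions}
    return MonomerProfile(MonomerKind.AMINO_ACID, fractions, masses)


def nt_profile_from_regions(
    genome_path: str,
    annotation_path: Optional[str],
    region_kind: str,
) -> MonomerProfile:
    """Nucleotide molar fractions from rRNA genes or the whole genome.

    ``region_kind="rRNA"``: AMP/CMP/GMP/UMP fractions over the rRNA gene
    sequences (T counted as U).  ``region_kind="whole_genome"``: dNMP
    fractions counted over both strands, so A pairs with T and G with C.
    """
    from Bio import SeqIO

    if region_kind == "rRNA":
        if annotation_path is None:
            raise ValueError("rRNA profile requires an annotation")
        db = _load_gff(annotation_path)
        counts = {"A": 0, "C": 0, "G": 0, "U": 0}
        n_feat = 0
        for feat in db.features_of_type("rRNA"):
            seq = feat.sequence(genome_path, use_strand=True).upper()
            for base in seq:
                if base == "T":
                    counts["U"] += 1
                elif base in counts:
                    counts[base] += 1
            n_feat += 1
        if n_feat == 0:
            raise ValueError("no rRNA features in annotation")
        total = sum(counts.values())
        key = {"A": "amp", "C": "cmp", "G": "gmp", "U": "ump"}
        fractions = {key[b]: c / total for b, c in counts.items()}
        return MonomerProfile(MonomerKind.RNA_NUCLEOTIDE, fractions, RNA_RESIDUE_MASSES)

    if region_kind == "whole_genome":
        counts = {"A": 0, "C": 0, "G": 0, "T": 0}
        for rec in SeqIO.parse(genome_path, "fasta"):
            for base in str(rec.seq).upper():
                if base in counts:
                    counts[base] += 1
        total = sum(counts.values())
        if total == 0:
            raise ValueError("empty genome")
        # both strands: A with T, G with C
        at = (counts["A"] + counts["T"]) / (2 * total)
        gc = (counts["G"] + counts["C"]) / (2 * total)
        fractions = {"damp": at, "dtmp": at, "dgmp": gc, "dcmp": gc}
        return MonomerProfile(MonomerKind.DNA_NUCLEOTIDE, fractions, DNA_RESIDUE_MASSES)

    raise ValueError(f"unknown region_kind {region_kind!r}")


# ---------------------------------------------------------------------------
# Biomass-reaction construction and sensitivity
# ---------------------------------------------------------------------------

_KIND_TO_COMPONENT = {
    MonomerKind.AMINO_ACID: "protein",
    MonomerKind.RNA_NUCLEOTIDE: "rna",
    MonomerKind.DNA_NUCLEOTIDE: "DNA",
}

DEFAULT_ENERGY_IDS = {
    "atp": "atp_c", "h2o": "h2o_c", "adp": "adp_c", "pi": "pi_c", "h": "h_c",
}


def _component_coefficients(
    comp: BiomassComposition,
    profiles: Sequence[MonomerProfile],
    lumped_masses: Mapping[str, float],
    metabolite_map: Mapping[str, str],
) -> Dict[str, Dict[str, float]]:
    """Per-component consumed coefficients in mmol/gCDW, keyed by metabolite id."""
    by_component: Dict[str, Dict[str, float]] = {}
    profiled = {}
    for prof in profiles:
        profiled[_KIND_TO_COMPONENT[prof.kind]] = prof
    for name, f in comp.fractions.items():
        if f == 0:
            continue
        coefs: Dict[str, float] = {}
        if name in profiled:
            prof = profiled[name]
            mbar = prof.mean_residue_mass()
            for monomer, phi in prof.fractions.items():
                mid = metabolite_map.get(monomer, f"{monomer}_c")
                coefs[mid] = 1000.0 * f * phi / mbar
        else:
            if name not in lumped_masses:
                raise ValueError(f"no molar mass for lumped biomass component {name!r}")
            mid = metabolite_map.get(name, f"{name}_c")
            coefs[mid] = 1000.0 * f / lumped_masses[name]
        by_component[name] = coefs
    return by_component


def build_biomass_reaction(
    comp: BiomassComposition,
    profiles: Sequence[MonomerProfile],
    lumped_masses: Optional[Mapping[str, float]] = None,
    metabolite_map: Optional[Mapping[str, str]] = None,
    energy_ids: Optional[Mapping[str, str]] = None,
    reaction_id: str = "BIOMASS",
    biomass_metabolite: Optional[str] = None,
) -> Reaction:
    """Assemble the biomass pseudo-reaction for one composition.

    For a polymer class with mass fraction f and monomer molar fractions
    phi_i (residue masses m_i), monomer i is consumed at
    1000 * f * phi_i / sum_j(phi_j m_j) mmol/gCDW; lumped components at
    1000 * f / M.  Growth-associated maintenance is appended as
    gam x (ATP + H2O -> ADP + Pi + H+).  Flux through the reaction is the
    growth rate in 1/h (1 g of components consumed per gCDW formed).
    """
    lumped = dict(DEFAULT_LUMPED_MASSES)
    if lumped_masses:
        lumped.update(lumped_masses)
    mmap = dict(metabolite_map or {})
    eids = dict(DEFAULT_ENERGY_IDS)
    if energy_ids:
        eids.update(energy_ids)

    groups = _component_coefficients(comp, profiles, lumped, mmap)
    stoich: Dict[str, float] = {}
    for coefs in groups.values():
        for mid, c in coefs.items():
            stoich[mid] = stoich.get(mid, 0.0) - c
    if comp.gam > 0:
        for key, sign in (("atp", -1), ("h2o", -1), ("adp", 1), ("pi", 1), ("h", 1)):
            mid = eids[key]
            stoich[mid] = stoich.get(mid, 0.0) + sign * comp.gam
    if biomass_metabolite is not None:
        stoich[biomass_metabolite] = stoich.get(biomass_metabolite, 0.0) + 1.0
    return Reaction(id=reaction_id, stoichiometry=stoich, lower_bound=0.0, upper_bound=1000.0)


def biomass_component_groups(
    comp: BiomassComposition,
    profiles: Sequence[MonomerProfile],
    lumped_masses: Optional[Mapping[str, float]] = None,
    metabolite_map: Optional[Mapping[str, str]] = None,
) -> Dict[str, List[str]]:
    """Metabolite ids of the biomass reaction grouped by biomass component."""
    lumped = dict(DEFAULT_LUMPED_MASSES)
    if lumped_masses:
        lumped.update(lumped_masses)
    groups = _component_coefficients(comp, profiles, lumped, dict(metabolite_map or {}))
    return {name: sorted(coefs) for name, coefs in groups.items()}


def sensitivity_scan(
    model: MetabolicModel,
    component_groups: Mapping[str, Sequence[str]],
    biomass_id: str = "BIOMASS",
    factor_range: Tuple[float, float] = (0.75, 1.25),
    grid: int = 11,
) -> float:
    """Max relative change in optimal biomass flux under per-component rescaling.

    Each listed component's biomass coefficients are scaled by factors on a
    grid spanning ``factor_range`` (no renormalization of the other
    components — the perturbation is to the mass fraction itself), the model
    re-solved, and the largest |Δμ|/μ over all components and factors
    returned.
    """
    base = fba(model)
    if base.status is not FluxStatus.OPTIMAL or base.objective_value <= 0:
        raise ModelError("base model does not grow; sensitivity undefined")
    mu0 = base.objective_value
    worst = 0.0
    for name, met_ids in component_groups.items():
        for factor in np.linspace(factor_range[0], factor_range[1], grid):
            perturbed = model.copy()
            rxn = perturbed.reaction(biomass_id)
            for mid in met_ids:
                if mid in rxn.stoichiometry:
                    rxn.stoichiometry[mid] *= factor
            sol = fba(perturbed)
            if sol.status is not FluxStatus.OPTIMAL:
                raise ModelError(f"perturbed model infeasible (component {name}, factor {factor:.3f})")
            worst = max(worst, abs(sol.objective_value - mu0) / mu0)
    return worst
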