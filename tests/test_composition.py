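from collections import Counter

import numpy as np
import pytest

from marinegem.composition import (
    AA_RESIDUE_MASSES,
    BiomassComposition,
    GrowthRateFits,
    LinearFit,
    MonomerKind,
    MonomerProfile,
    OsmolyteSpec,
    ReferenceRemainder,
    aa_profile_from_genome,
    biomass_component_groups,
    build_biomass_reaction,
    composition_at,
    nt_profile_from_regions,
    reference_fits,
    reference_remainder,
    sensitivity_scan,
)
from marinegem.model_core import Compartment, Metabolite, MetabolicModel, Reaction, fba


class TestCompositionAt:
    @pytest.mark.parametrize(
        "gr",
        [0.79, 0.28],
    )
    def test_matches_direct_fit_evaluation(self, gr):
        # oracle: evaluate the printed lines by hand and divide
        fits = reference_fits()
        protein = (-0.09 * gr + 0.38) / (-0.13 * gr + 0.64)
        rna = (0.05 * gr + 0.05) / (-0.13 * gr + 0.64)
        comp = composition_at(gr, fits, OsmolyteSpec(0.050, 0.0))
        assert comp.fractions["protein"] == pytest.approx(protein, rel=1e-12)
        assert comp.fractions["rna"] == pytest.approx(rna, rel=1e-12)
        assert comp.fractions["glutamate"] == pytest.approx(0.050)
        remainder_total = sum(
            comp.fractions[k] for k in ("DNA", "LPS", "lipid", "murein", "inorganic_ions", "soluble_pool")
        )
        assert remainder_total == pytest.approx(1.0 - protein - rna - 0.050, rel=1e-9)

    def test_reference_values_at_glucose_growth_rate(self):
        comp = composition_at(0.79, reference_fits(), OsmolyteSpec(0.050, 0.0))
        assert comp.fractions["protein"] == pytest.approx(0.575, abs=5e-4)
        assert comp.fractions["rna"] == pytest.approx(0.167, abs=5e-4)

    def test_rna_fraction_rises_with_growth_rate(self):
        fits = reference_fits()
        slow = composition_at(0.28, fits)
        fast = composition_at(0.79, fits)
        assert fast.fractions["rna"] > slow.fractions["rna"]

    def test_fractions_sum_to_one_over_range(self):
        fits = reference_fits()
        rng = np.random.default_rng(11)
        for gr in rng.uniform(0.0, fits.gr_max, 100):
            comp = composition_at(float(gr), fits)
            assert sum(comp.fractions.values()) == pytest.approx(1.0, abs=1e-6)
            assert all(f >= 0 for f in comp.fractions.values())

    def test_zero_slope_fits_are_growth_rate_independent(self):
        fits = GrowthRateFits(LinearFit(0.0, 0.1), LinearFit(0.0, 0.3), LinearFit(0.0, 0.6))
        a = composition_at(0.1, fits)
        b = composition_at(1.0, fits)
        assert a.fractions == pytest.approx(b.fractions)

    def test_overfull_measured_components_rejected(self):
        fits = GrowthRateFits(LinearFit(0.0, 0.40), LinearFit(0.0, 0.42), LinearFit(0.0, 0.90))
        with pytest.raises(ValueError, match="exceed"):
            composition_at(0.5, fits, OsmolyteSpec(0.2, 0.0))

    def test_remainder_keeps_reference_proportions(self):
        comp = composition_at(0.79, reference_fits())
        ref = reference_remainder()
        ratio = comp.fractions["lipid"] / comp.fractions["DNA"]
        assert ratio == pytest.approx(ref.components["lipid"] / ref.components["DNA"], rel=1e-6)


class TestGenomeProfiles:
    def test_single_cds_hand_translation(self, tmp_path):
        fasta = tmp_path / "g.fa"
        fasta.write_text(">c1\nATGGCTGCTTAA\n")
        gff = tmp_path / "g.gff3"
        gff.write_text("##gff-version 3\nc1\tsrc\tCDS\t1\t12\t.\t+\t0\tID=x\n")
        prof = aa_profile_from_genome(str(fasta), str(gff))
        assert prof.fractions["M"] == pytest.approx(1 / 3)
        assert prof.fractions["A"] == pytest.approx(2 / 3)

    def test_counts_match_brute_force_codon_tally(self, genome_files):
        fasta, gff = genome_files
        prof = aa_profile_from_genome(fasta, gff)
        # brute-force oracle: hand-coded translations of the three CDS
        expected = Counter("MAA") + Counter("MK") + Counter("MG")
        total = sum(expected.values())
        for aa, n in expected.items():
            assert prof.fractions[aa] == pytest.approx(n / total, rel=1e-12)
        assert sum(prof.fractions.values()) == pytest.approx(1.0)

    def test_minus_strand_equivalent_to_plus(self, tmp_path):
        plus = tmp_path / "plus.fa"
        plus.write_text(">c\nATGGGCTAA\n")
        gplus = tmp_path / "plus.gff3"
        gplus.write_text("##gff-version 3\nc\tsrc\tCDS\t1\t9\t.\t+\t0\tID=a\n")
        rc = "ATGGGCTAA".translate(str.maketrans("ACGT", "TGCA"))[::-1]
        minus = tmp_path / "minus.fa"
        minus.write_text(f">c\n{rc}\n")
        gminus = tmp_path / "minus.gff3"
        gminus.write_text("##gff-version 3\nc\tsrc\tCDS\t1\t9\t.\t-\t0\tID=a\n")
        assert aa_profile_from_genome(str(plus), str(gplus)).fractions == pytest.approx(
            aa_profile_from_genome(str(minus), str(gminus)).fractions
        )

    def test_frameshifted_cds_skipped_with_warning(self, tmp_path):
        fasta = tmp_path / "g.fa"
        fasta.write_text(">c\nATGGCTGCTTAAAC\n")
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c\tsrc\tCDS\t1\t12\t.\t+\t0\tID=ok\n"
            "c\tsrc\tCDS\t1\t14\t.\t+\t0\tID=bad\n"
        )
        with pytest.warns(UserWarning, match="divisible"):
            prof = aa_profile_from_genome(str(fasta), str(gff))
        assert prof.fractions["A"] == pytest.approx(2 / 3)

    def test_no_usable_cds_rejected(self, tmp_path):
        fasta = tmp_path / "g.fa"
        fasta.write_text(">c\nACGTACGT\n")
        gff = tmp_path / "g.gff3"
        gff.write_text("##gff-version 3\nc\tsrc\tgene\t1\t8\t.\t+\t.\tID=g\n")
        with pytest.raises(ValueError, match="CDS"):
            aa_profile_from_genome(str(fasta), str(gff))

    def test_rrna_uniform_sequence(self, tmp_path):
        fasta = tmp_path / "g.fa"
        fasta.write_text(">c\nACGTAAAA\n")
        gff = tmp_path / "g.gff3"
        gff.write_text("##gff-version 3\nc\tsrc\trRNA\t1\t4\t.\t+\t.\tID=r\n")
        prof = nt_profile_from_regions(str(fasta), str(gff), "rRNA")
        assert all(prof.fractions[k] == pytest.approx(0.25) for k in ("amp", "cmp", "gmp", "ump"))

    def test_two_rrna_hand_tally(self, genome_files):
        fasta, gff = genome_files
        prof = nt_profile_from_regions(fasta, gff, "rRNA")
        # rRNA1 = ACGT, rRNA2 = AACCGG -> A:3 C:3 G:3 U:1 of 10
        assert prof.fractions["amp"] == pytest.approx(0.3)
        assert prof.fractions["cmp"] == pytest.approx(0.3)
        assert prof.fractions["gmp"] == pytest.approx(0.3)
        assert prof.fractions["ump"] == pytest.approx(0.1)

    def test_whole_genome_double_strand_symmetry(self, tmp_path):
        fasta = tmp_path / "g.fa"
        fasta.write_text(">c\nAAGG\n")
        prof = nt_profile_from_regions(str(fasta), None, "whole_genome")
        assert prof.fractions["damp"] == pytest.approx(0.25)
        assert prof.fractions["dtmp"] == pytest.approx(0.25)
        assert prof.fractions["dgmp"] == pytest.approx(0.25)
        assert prof.fractions["dcmp"] == pytest.approx(0.25)

    def test_missing_rrna_rejected(self, tmp_path):
        fasta = tmp_path / "g.fa"
        fasta.write_text(">c\nACGT\n")
        gff = tmp_path / "g.gff3"
        gff.write_text("##gff-version 3\nc\tsrc\tgene\t1\t4\t.\t+\t.\tID=g\n")
        with pytest.raises(ValueError, match="rRNA"):
            nt_profile_from_regions(str(fasta), str(gff), "rRNA")

    def test_gene_order_invariance(self, genome_files, tmp_path):
        fasta, gff = genome_files
        lines = open(gff).read().strip().splitlines()
        shuffled = [lines[0]] + lines[1:][::-1]
        gff2 = tmp_path / "shuffled.gff3"
        gff2.write_text("\n".join(shuffled) + "\n")
        assert aa_profile_from_genome(fasta, gff).fractions == pytest.approx(
            aa_profile_from_genome(fasta, str(gff2)).fractions
        )


def make_composition(fractions, gam=0.0, gr=0.5):
    return BiomassComposition(fractions=fractions, gam=gam, growth_rate=gr)


class TestBuildBiomassReaction:
    def test_single_monomer_closed_form(self):
        prof = MonomerProfile(MonomerKind.AMINO_ACID, {"G": 1.0}, {"G": 100.0})
        comp = make_composition({"protein": 0.5, "soluble_pool": 0.5})
        rxn = build_biomass_reaction(comp, [prof])
        assert rxn.stoichiometry["G_c"] == pytest.approx(-5.0, rel=1e-12)

    def test_two_monomer_mean_mass(self):
        prof = MonomerProfile(MonomerKind.AMINO_ACID, {"G": 0.5, "A": 0.5}, {"G": 100.0, "A": 200.0})
        comp = make_composition({"protein": 0.3, "soluble_pool": 0.7})
        rxn = build_biomass_reaction(comp, [prof])
        assert rxn.stoichiometry["G_c"] == pytest.approx(-1.0, rel=1e-12)
        assert rxn.stoichiometry["A_c"] == pytest.approx(-1.0, rel=1e-12)

    def test_gam_appended_as_atp_hydrolysis(self):
        prof = MonomerProfile(MonomerKind.AMINO_ACID, {"G": 1.0}, {"G": 100.0})
        comp = make_composition({"protein": 1.0}, gam=15.8)
        rxn = build_biomass_reaction(comp, [prof])
        assert rxn.stoichiometry["atp_c"] == pytest.approx(-15.8)
        assert rxn.stoichiometry["h2o_c"] == pytest.approx(-15.8)
        assert rxn.stoichiometry["adp_c"] == pytest.approx(15.8)
        assert rxn.stoichiometry["pi_c"] == pytest.approx(15.8)
        assert rxn.stoichiometry["h_c"] == pytest.approx(15.8)

    def test_mass_balance_recovers_class_fractions(self):
        """sum(coef * residue mass) over a polymer class equals 1000*f."""
        aa = MonomerProfile(
            MonomerKind.AMINO_ACID,
            {"G": 0.25, "A": 0.5, "K": 0.25},
            {k: AA_RESIDUE_MASSES[k] for k in ("G", "A", "K")},
        )
        comp = make_composition({"protein": 0.6, "soluble_pool": 0.4})
        rxn = build_biomass_reaction(comp, [aa])
        total = sum(
            -rxn.stoichiometry[f"{m}_c"] * aa.residue_masses[m] for m in aa.fractions
        )
        assert total == pytest.approx(1000 * 0.6, rel=1e-9)

    def test_missing_lumped_mass_rejected(self):
        comp = make_composition({"protein": 0.5, "mystery": 0.5})
        prof = MonomerProfile(MonomerKind.AMINO_ACID, {"G": 1.0}, {"G": 100.0})
        with pytest.raises(ValueError, match="mystery"):
            build_biomass_reaction(comp, [prof])


class TestSensitivityScan:
    @pytest.fixture()
    def scan_model(self):
        """Growth limited by substrate A; component 'pool' drawn from an
        unlimited parallel source, so rescaling it cannot move the optimum."""
        C, E = Compartment.CYTOPLASM, Compartment.EXTRACELLULAR
        mets = [Metabolite("a_e", E), Metabolite("a_c", C), Metabolite("p_c", C)]
        rxns = [
            Reaction("EX_a", {"a_e": -1.0}, -10.0, 1000.0),
            Reaction("T_a", {"a_e": -1.0, "a_c": 1.0}, 0.0, 1000.0),
            Reaction("MAKE_p", {"p_c": 1.0}, 0.0, 1000.0),
            Reaction("BIOMASS", {"a_c": -1.0, "p_c": -0.1}, 0.0, 1000.0),
        ]
        return MetabolicModel(mets, rxns, objective_id="BIOMASS")

    def test_identity_factor_changes_nothing(self, scan_model):
        assert sensitivity_scan(
            scan_model, {"pool": ["p_c"]}, factor_range=(1.0, 1.0), grid=1
        ) == pytest.approx(0.0, abs=1e-9)

    def test_non_limiting_component_is_insensitive(self, scan_model):
        change = sensitivity_scan(scan_model, {"pool": ["p_c"]})
        assert change < 1e-6

    def test_limiting_component_is_sensitive(self, scan_model):
        change = sensitivity_scan(scan_model, {"carbon": ["a_c"]})
        # scaling the limiting coefficient by 0.75 raises mu by 1/3
        assert change == pytest.approx(1.0 / 3.0, rel=1e-6)

    def test_wider_range_never_decreases_reported_change(self, scan_model):
        narrow = sensitivity_scan(scan_model, {"carbon": ["a_c"]}, factor_range=(0.9, 1.1), grid=5)
        wide = sensitivity_scan(scan_model, {"carbon": ["a_c"]}, factor_range=(0.75, 1.25), grid=5)
        assert wide >= narrow - 1e-12

    def test_infeasible_base_rejected(self, scan_model):
        m = scan_model.copy()
        m.reaction("EX_a").lower_bound = 0.0
        m.reaction("EX_a").upper_bound = 0.0
        with pytest.raises(Exception, match="grow"):
            sensitivity_scan(m, {"pool": ["p_c"]})

    def test_groups_cover_composition_components(self):
        profiles = [
            MonomerProfile(MonomerKind.AMINO_ACID, {"G": 1.0}, {"G": 100.0}),
            MonomerProfile(MonomerKind.RNA_NUCLEOTIDE, {"amp": 1.0}, {"amp": 329.2}),
            MonomerProfile(MonomerKind.DNA_NUCLEOTIDE, {"damp": 1.0}, {"damp": 313.2}),
        ]
        comp = composition_at(0.79, reference_fits())
        groups = biomass_component_groups(comp, profiles)
        assert groups["protein"] == ["G_c"]
        assert groups["rna"] == ["amp_c"]
        assert groups["glutamate"] == ["glutamate_c"]
        assert set(groups) == {k for k, f in comp.fractions.items() if f > 0}
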