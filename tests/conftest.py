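import textwrap

import pytest

from marinegem.model_core import Compartment, Metabolite, MetabolicModel, Reaction
from marinegem.synthetic_data import SubstrateSpec, ToyNetworkSpec, make_toy_model


@pytest.fixture(scope="session")
def toy_spec() -> ToyNetworkSpec:
    return ToyNetworkSpec()


@pytest.fixture(scope="session")
def toy_model(toy_spec):
    return make_toy_model(toy_spec)


@pytest.fixture()
def small_fixture_model() -> MetabolicModel:
    """Hand-countable model: 2 exchanges, 3 transport, 2 internal reactions;
    metabolites 3 cytoplasmic / 1 periplasmic / 2 extracellular.  Maximal
    flux through EX_b equals the uptake cap of 10."""
    C, P, E = Compartment.CYTOPLASM, Compartment.PERIPLASM, Compartment.EXTRACELLULAR
    mets = [
        Metabolite("s_e", E), Metabolite("s_p", P), Metabolite("s_c", C),
        Metabolite("a_c", C), Metabolite("b_c", C), Metabolite("b_e", E),
    ]
    rxns = [
        Reaction("EX_s", {"s_e": -1.0}, -10.0, 1000.0),
        Reaction("EX_b", {"b_e": -1.0}, 0.0, 1000.0),
        Reaction("T_s1", {"s_e": -1.0, "s_p": 1.0}, -1000.0, 1000.0),
        Reaction("T_s2", {"s_p": -1.0, "s_c": 1.0}, 0.0, 1000.0),
        Reaction("T_b", {"b_c": -1.0, "b_e": 1.0}, 0.0, 1000.0),
        Reaction("R1", {"s_c": -1.0, "a_c": 1.0}, 0.0, 1000.0),
        Reaction("R2", {"a_c": -1.0, "b_c": 1.0}, 0.0, 1000.0),
    ]
    return MetabolicModel(mets, rxns, objective_id="EX_b")


@pytest.fixture()
def genome_files(tmp_path):
    """Two-contig genome plus GFF3: two plus-strand CDS, one minus-strand CDS,
    two rRNA genes.  Translations are short enough to tally by hand."""
    # contig1: CDS1 at 1..12 = ATGGCTGCTTAA -> MAA (stop dropped)
    #          rRNA1 at 13..16 = ACGT
    # contig2: CDS2 at 1..9 = ATGAAATGA? use ATGAAATAA -> MK
    #          CDS3 minus strand at 10..18, genome holds revcomp of ATGGGCTAA
    #          rRNA2 at 19..24 = AACCGG
    contig1 = "ATGGCTGCTTAA" + "ACGT"
    cds3_fwd = "ATGGGCTAA"  # -> MG
    revcomp = cds3_fwd.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    contig2 = "ATGAAATAA" + revcomp + "AACCGG"
    fasta = tmp_path / "genome.fa"
    fasta.write_text(f">contig1\n{contig1}\n>contig2\n{contig2}\n")
    gff = tmp_path / "genome.gff3"
    gff.write_text(textwrap.dedent("""\
        ##gff-version 3
        contig1\tsrc\tCDS\t1\t12\t.\t+\t0\tID=cds1
        contig1\tsrc\trRNA\t13\t16\t.\t+\t.\tID=rrna1
        contig2\tsrc\tCDS\t1\t9\t.\t+\t0\tID=cds2
        contig2\tsrc\tCDS\t10\t18\t.\t-\t0\tID=cds3
        contig2\tsrc\trRNA\t19\t24\t.\t+\t.\tID=rrna2
        """))
    return str(fasta), str(gff)
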