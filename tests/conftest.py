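import pytest

from splicecase import synthetic_data as sd
from splicecase.editing_feasibility import load_nuclease_catalog


@pytest.fixture(scope="session")
def nf1_case():
    """Synthetic mirror of the NF1 c.61-2A>G acceptor-variant geometry."""
    return sd.nf1_like_case()


@pytest.fixture(scope="session")
def catalog():
    return load_nuclease_catalog()


@pytest.fixture()
def toy_two_exon():
    """Tiny two-exon plus-strand gene for hand-checkable coordinate walks.

    Layout (1-based): exon1 = 100..159 (60 coding nt starting ATG),
    intron = 160..189 (GT..AG), exon2 = 190..249.
    """
    from splicecase.genome_io import GeneModel, GenomeSequence

    exon1 = "ATG" + "CTG" * 19
    intron = "GT" + "C" * 10 + "T" * 16 + "AG"  # 30 nt: 160..189
    exon2 = "CTT" * 19 + "TAA"
    seq = "G" * 99 + exon1 + intron + exon2 + "G" * 20
    genome = GenomeSequence("chrT", seq, 1)
    gene = GeneModel("TOY", "TOY-T1", "chrT", "+",
                     exons=((100, 159), (190, 249)),
                     cds_start=100, cds_end=249)
    return genome, gene
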