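import pytest

from salviacirc import simdata
from salviacirc.backsplice import GenomeKmerIndex
from salviacirc.models import GeneModel, GenomeModel, SampleDesign


@pytest.fixture(scope="session")
def toy_gene():
    """Three-exon plus-strand gene: E1[101,200], E2[301,400], E3[501,600]."""
    return GeneModel(
        gene_id="G", scaffold="scf1", strand="+",
        exons=((101, 200), (301, 400), (501, 600)),
    )


@pytest.fixture(scope="session")
def small_genome():
    return simdata.simulate_genome(
        n_scaffolds=2, scaffold_len=30_000, n_genes=8, exons_per_gene=(2, 4), seed=11
    )


@pytest.fixture(scope="session")
def planted(small_genome):
    """Small end-to-end simulation shared by detection/annotation tests."""
    truth = simdata.plant_circrnas(small_genome, 6, 2, 2, seed=11)
    design = SampleDesign(replicates=2)
    sim = simdata.simulate_reads(
        small_genome, truth, design, seed=11, min_junction_reads=3
    )
    return small_genome, truth, design, sim


@pytest.fixture(scope="session")
def small_index(small_genome):
    return GenomeKmerIndex(small_genome)
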