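import pytest

from tadfunc.genome_model import Domain, DomainPartition, Gene, GenomicInterval, assign_genes, derive_gaps
from tadfunc.go_similarity import GoDag, TermSimConfig
from tadfunc.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def dataset():
    """The default positive-control synthetic dataset, seed 0."""
    return simulate(SimConfig(seed=0))


@pytest.fixture
def toy_dag():
    """Root R with children A, B; C below A.  All is_a except B (part_of)."""
    parents = {
        "GO:0008150": [],
        "A": [("GO:0008150", "is_a")],
        "B": [("GO:0008150", "part_of")],
        "C": [("A", "is_a")],
    }
    ns = {t: "BPO" for t in parents}
    return GoDag(parents, ns)


@pytest.fixture
def wang_config():
    return TermSimConfig(measure="wang", w_is_a=0.8, w_part_of=0.6)


@pytest.fixture
def toy_partition():
    """Three TADs with a gap, seven genes (one per spec of positions)."""
    chrom = "chr1"
    tads = [
        Domain("tad", 1, GenomicInterval(chrom, 0, 100)),
        Domain("tad", 2, GenomicInterval(chrom, 150, 250)),
        Domain("tad", 3, GenomicInterval(chrom, 250, 350)),
    ]
    gaps, dropped = derive_gaps(tads)
    genes = [
        Gene("g1", GenomicInterval(chrom, 10, 20)),
        Gene("g2", GenomicInterval(chrom, 30, 40)),
        Gene("g3", GenomicInterval(chrom, 60, 90)),
        Gene("g4", GenomicInterval(chrom, 160, 200)),
        Gene("g5", GenomicInterval(chrom, 210, 240)),
        Gene("g6", GenomicInterval(chrom, 260, 300)),
        Gene("g7", GenomicInterval(chrom, 120, 140)),  # inside the gap
    ]
    partition = DomainPartition(chrom, tads, gaps, dropped_zero_gaps=dropped)
    return assign_genes(genes, partition)
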