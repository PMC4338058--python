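import pytest

from srna_seeker.annotation_io import AnnotatedGenome, GeneFeature
from srna_seeker.synthetic_data import SimConfig, simulate_genome, simulate_reads


@pytest.fixture
def toy_genome():
    """Linear 2000 bp genome with two CDS genes, gap [500, 900)."""
    seq = ("ACGT" * 500)
    features = [
        GeneFeature("geneA", "CDS", 100, 500, "+", "protein A"),
        GeneFeature("geneB", "CDS", 900, 1500, "-", "protein B"),
    ]
    return AnnotatedGenome("toy", seq, is_circular=False, features=features)


@pytest.fixture(scope="session")
def sim_default():
    """One default simulated genome + truth + reads, shared across tests."""
    cfg = SimConfig(seed=11)
    genome, truth = simulate_genome(cfg)
    reads = simulate_reads(genome, truth, cfg)
    return cfg, genome, truth, reads
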