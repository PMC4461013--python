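import numpy as np
import pytest

from splicepipe.annotation import AnnotationSet, Exon, GenomicInterval, Transcript
from splicepipe.simulate import SimConfig, make_toy_genome_annotation, simulate_reads


def make_transcript(tid, gene, chrom, strand, intervals):
    """Build a transcript from genomic (start, end) pairs; exon ranks follow
    strand-aware transcript order."""
    ivs = sorted(intervals, reverse=(strand == "-"))
    exons = [
        Exon(GenomicInterval(chrom, s, e, strand), rank)
        for rank, (s, e) in enumerate(ivs, start=1)
    ]
    return Transcript(tid, gene, chrom, strand, exons)


@pytest.fixture
def toy_genome():
    """Deterministic 6 kb chromosome."""
    rng = np.random.default_rng(11)
    return {"chr1": "".join(rng.choice(list("ACGT"), size=6000))}


@pytest.fixture
def three_exon_tx():
    return make_transcript(
        "T1", "G1", "chr1", "+", [(100, 200), (400, 480), (700, 730)]
    )


@pytest.fixture
def toy_annotation(three_exon_tx):
    ann = AnnotationSet()
    ann.add(three_exon_tx)
    ann.add(
        make_transcript("T2", "G2", "chr1", "-", [(1000, 1150), (1400, 1500), (1800, 1900), (2200, 2320)])
    )
    return ann


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """One error-free simulated experiment shared across tests."""
    cfg = SimConfig(seed=5)
    genome, ann = make_toy_genome_annotation(cfg)
    outdir = tmp_path_factory.mktemp("sim")
    sim = simulate_reads(genome, ann, cfg, outdir)
    return cfg, genome, ann, sim
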