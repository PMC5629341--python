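import numpy as np
import pytest

from ltrcall import detection as D
from ltrcall import synthetic_data as S
from ltrcall.formats_io import AnnotationModel, Gene, GenomicInterval, TEFeature


@pytest.fixture(scope="session")
def default_sim():
    """One full synthetic experiment at study conditions (seed 0)."""
    cfg = S.SimulationConfig()
    rng = np.random.default_rng(0)
    toy = S.build_toy_genome(cfg, rng)
    mutated = S.plant_insertions(toy, cfg, rng)
    te_ivs = [t.interval for t in toy.annotation.te_features]
    reads = S.simulate_alignments(mutated, te_ivs, cfg, rng)
    return cfg, toy, mutated, reads


@pytest.fixture(scope="session")
def default_calls(default_sim):
    cfg, toy, mutated, reads = default_sim
    te_ivs = [t.interval for t in toy.annotation.te_features]
    calls = D.detect_insertions(reads, toy.assembly, toy.te, te_ivs)
    return calls


@pytest.fixture(scope="session")
def tiny_te():
    return S.build_te_consensus(np.random.default_rng(11), element_len=1000, ltr_len=120)


@pytest.fixture()
def hand_annotation():
    """Two genes on chr1 plus one TE feature, for classification tests.

    geneA: + strand, [1000, 3000): 5'UTR [1000,1200), exons [1200,1700) and
    [2000,2800), intron [1700,2000), 3'UTR [2800,3000).
    geneB: - strand, [6000, 8000) with one exon body.
    TE feature at [9000, 9500).
    """
    ga = Gene(
        "geneA", GenomicInterval("chr1", 1000, 3000, "+"), "+",
        exons=[GenomicInterval("chr1", 1200, 1700, "+"), GenomicInterval("chr1", 2000, 2800, "+")],
        utr5=GenomicInterval("chr1", 1000, 1200, "+"),
        utr3=GenomicInterval("chr1", 2800, 3000, "+"),
    )
    gb = Gene(
        "geneB", GenomicInterval("chr1", 6000, 8000, "-"), "-",
        exons=[GenomicInterval("chr1", 6200, 7800, "-")],
        utr5=GenomicInterval("chr1", 7800, 8000, "-"),
        utr3=GenomicInterval("chr1", 6000, 6200, "-"),
    )
    te = TEFeature("te1", GenomicInterval("chr1", 9000, 9500, "+"))
    return AnnotationModel([ga, gb], [te])
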