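import numpy as np
import pytest

from ncscreen import simulate
from ncscreen.intervals import AnnotatedFeature, AnnotationSet, GenomicInterval


@pytest.fixture(scope="session")
def small_ann() -> AnnotationSet:
    """Tiny hand-built annotation on a 2 kb sequence."""
    feats = [
        AnnotatedFeature(GenomicInterval("chr", 100, 400, "+"), "geneA", "coding_gene"),
        AnnotatedFeature(GenomicInterval("chr", 600, 900, "+"), "geneB", "coding_gene"),
        AnnotatedFeature(GenomicInterval("chr", 300, 700, "-"), "geneC", "coding_gene"),
        AnnotatedFeature(GenomicInterval("chr", 1200, 1500, "-"), "rrna1", "rRNA"),
    ]
    return AnnotationSet(features=feats, seq_lengths={"chr": 2000})


@pytest.fixture(scope="session")
def synth_ann() -> AnnotationSet:
    return simulate.make_annotation(seed=1, n_genes=100, genome_length=200_000)


@pytest.fixture(scope="session")
def synth_plants(synth_ann):
    return simulate.plant_ntrs(synth_ann, seed=2)


@pytest.fixture(scope="session")
def counts_sim():
    """One 2000-gene count simulation shared across DE tests."""
    return simulate.simulate_counts(n_genes=2000, fraction_de=0.10, seed=11)


def jaccard(a: GenomicInterval, b: GenomicInterval) -> float:
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    union = len(a) + len(b) - inter
    return inter / union


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
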