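import numpy as np
import pytest

from qtlcanvas.coords import GenomicInterval, TranscriptModel
from qtlcanvas.synthfix import SimConfig


@pytest.fixture
def two_exon_map_exons():
    """The canonical worked example: 100 bp exon, 300 bp intron, 100 bp exon."""
    return [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 500, 600)]


@pytest.fixture
def small_transcript():
    return TranscriptModel(
        "GENE1", "GENE1.t1",
        (
            GenomicInterval("chr1", 100, 200, "+"),
            GenomicInterval("chr1", 500, 600, "+"),
            GenomicInterval("chr1", 900, 1000, "+"),
        ),
    )


@pytest.fixture
def sim_cfg():
    """Small, fast simulation config for unit tests."""
    return SimConfig(seed=7, n_samples=60, n_groups=20)


def random_exon_structure(rng: np.random.Generator, max_exons: int = 20):
    """Random sorted, disjoint exon list (shared by property tests)."""
    n = int(rng.integers(1, max_exons + 1))
    pos = int(rng.integers(0, 1000))
    exons = []
    for _ in range(n):
        length = int(rng.integers(1, 500))
        exons.append(GenomicInterval("chrT", pos, pos + length))
        pos += length + int(rng.integers(1, 3000))
    return exons
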