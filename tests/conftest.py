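import numpy as np
import pytest

from interband_scope.io_core import (
    Anchor,
    AnchorSet,
    BindingTrack,
    GenomeBuild,
    GenomicInterval,
)


@pytest.fixture
def toy_genome() -> GenomeBuild:
    return GenomeBuild((("chrA", 100_000), ("chrB", 50_000)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_track(protein, triples):
    """Track from (chrom, start, end[, score]) tuples."""
    intervals = []
    for t in triples:
        chrom, start, end = t[:3]
        score = t[3] if len(t) > 3 else 1.0
        intervals.append(GenomicInterval(chrom, start, end, score))
    return BindingTrack.from_intervals(protein, intervals)


def random_track(rng, protein="t", chrom="chrA", n=20, arm_len=100_000,
                 max_len=3000, scored=True):
    intervals = []
    for _ in range(n):
        length = int(rng.integers(50, max_len))
        start = int(rng.integers(0, arm_len - length))
        score = float(rng.normal()) if scored else 1.0
        intervals.append(GenomicInterval(chrom, start, start + length, score))
    return BindingTrack.from_intervals(protein, intervals)


@pytest.fixture
def anchors_13() -> AnchorSet:
    """13 anchors with the reference per-arm histogram 1/3/4/5."""
    spec = [("chr2R", 1), ("chr3L", 3), ("chr3R", 4), ("chrX", 5)]
    anchors = []
    i = 0
    for arm, count in spec:
        for j in range(count):
            i += 1
            anchors.append(Anchor(f"R{i}", arm, 100_000 + 50_000 * j))
    return AnchorSet(tuple(anchors))
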