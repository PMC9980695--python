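import numpy as np
import pytest

from epiconcord.core import (
    BinnedTrack,
    DifferentialRegion,
    Gene,
    Genome,
    GenomicInterval,
)


@pytest.fixture
def genome():
    return Genome(("chr1", "chr2"), (1_000_000, 800_000))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_track(genome):
    counts = {c: np.ones(genome.n_bins(c, 50), dtype=np.int64)
              for c in genome.names}
    return BinnedTrack.from_counts(genome, 50, counts)


def make_region(chrom, start, end, direction="gain", fold=2.5, p=0.001,
                mark="H3K27ac", name=""):
    return DifferentialRegion(GenomicInterval(chrom, start, end), direction,
                              fold, p, mark=mark, name=name)


def random_regions(rng, genome, n, min_w=100, max_w=2000, mark="H3K27ac"):
    out = []
    for i in range(n):
        chrom = genome.names[int(rng.integers(len(genome.names)))]
        clen = genome.length_of(chrom)
        w = int(rng.integers(min_w, max_w))
        s = int(rng.integers(0, clen - w))
        out.append(DifferentialRegion(
            GenomicInterval(chrom, s, s + w),
            "gain" if rng.random() < 0.5 else "loss",
            float(np.round(rng.uniform(2, 10), 4)),
            float(np.round(rng.uniform(1e-6, 0.01), 8)),
            mark=mark,
            name=f"r{i}",
        ))
    return out


@pytest.fixture
def region_factory():
    return make_region


@pytest.fixture
def random_region_factory():
    return random_regions
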