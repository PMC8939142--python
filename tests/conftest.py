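import numpy as np
import pytest

from breakscape.genome_model import BreakSet, GenomicInterval, merge
from breakscape.synthetic import SyntheticConfig, generate_genome


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_genome():
    """A small but complete synthetic genome shared across tests."""
    cfg = SyntheticConfig(
        seed=7,
        chrom_lengths={"chr1": 400_000, "chr2": 400_000},
        n_genes=60,
        gene_length_range=(2_000, 8_000),
        top_q_genes=15,
        n_h3k27ac_peaks=80,
        n_ctcf_peaks=100,
    )
    return cfg, generate_genome(cfg)


def random_breaks(rng, n, chroms=("chr1", "chr2"), span=100_000, sample="s"):
    pos = {c: rng.integers(0, span, size=rng.integers(0, n + 1)) for c in chroms}
    return BreakSet(sample, pos)


def random_regions(rng, n, chroms=("chr1", "chr2"), span=100_000, max_len=2_000):
    ivals = []
    for _ in range(n):
        c = chroms[int(rng.integers(len(chroms)))]
        s = int(rng.integers(0, span))
        e = s + int(rng.integers(1, max_len))
        ivals.append(GenomicInterval(c, s, e))
    return merge(ivals, name="random")


def brute_force_point_in_intervals(pos, intervals):
    """O(n*m) oracle: is the point inside any (start, end) pair."""
    return any(s <= pos < e for s, e in intervals)
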