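import numpy as np
import pytest

from cdxreg import GeneModel, GenomicInterval


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=100_000, max_len=2_000,
                     with_intensity=True):
    out = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        intensity = float(rng.lognormal(1.0, 0.8)) if with_intensity else 0.0
        out.append(GenomicInterval(chrom, start, start + length, intensity, f"iv{i:04d}"))
    return sorted(out)


def random_genes(rng, n, chroms=("chr1", "chr2"), span=100_000):
    return sorted(
        GeneModel(f"g{i:04d}", chroms[rng.integers(len(chroms))],
                  int(rng.integers(0, span)), "+" if rng.random() < 0.5 else "-")
        for i in range(n)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_genome():
    from cdxreg import gen_genome

    return gen_genome(2, 10_000_000, 100, seed=11)
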