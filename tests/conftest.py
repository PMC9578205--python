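import numpy as np
import pytest

from felipop.genomatrix import GenotypeMatrix, PopulationMap, Variant

BASES = "ACGT"


def make_gm(calls, positions=None, chrom="chr1", samples=None, phased=True,
            chroms=None):
    """Build a GenotypeMatrix from a (n_var, n_samp, 2) array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_var, n_samp, _ = calls.shape
    if positions is None:
        positions = np.arange(n_var) * 100
    if chroms is None:
        chroms = [chrom] * n_var
    if samples is None:
        samples = [f"s{i}" for i in range(n_samp)]
    variants = [
        Variant(c, int(p), "A", "C") for c, p in zip(chroms, positions)
    ]
    return GenotypeMatrix(variants, samples, calls, phased=phased)


def random_gm(rng, n_var=50, n_samp=8, miss=0.0, chrom="chr1", phased=True,
              spacing=100):
    calls = rng.integers(0, 2, size=(n_var, n_samp, 2)).astype(np.int8)
    if miss > 0:
        m = rng.random((n_var, n_samp)) < miss
        calls[m] = -1
    pos = np.sort(rng.choice(n_var * spacing * 2, size=n_var, replace=False))
    return make_gm(calls, positions=pos, chrom=chrom, phased=phased)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def two_group_pm():
    return PopulationMap(
        {f"s{i}": ("G1" if i < 4 else "G2") for i in range(8)}
    )
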