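import numpy as np
import pytest

from yakpop.genotype_io import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20151222)


def make_gm(dosages, pops=None, chrom="chr1", start_pos=100, spacing=100):
    """Small GenotypeMatrix from a (sites x samples) dosage array."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_sites, n_samples = dosages.shape
    if pops is None:
        half = n_samples // 2
        pops = ["W"] * half + ["D2"] * (n_samples - half)
    samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(
        samples,
        dict(zip(samples, pops)),
        np.array([chrom] * n_sites, dtype=object),
        np.arange(start_pos, start_pos + n_sites * spacing, spacing, dtype=np.int64),
        np.array(["A"] * n_sites, dtype=object),
        np.array(["G"] * n_sites, dtype=object),
        dosages,
    )


@pytest.fixture
def small_gm():
    # 6 sites x 8 samples (4 W, 2 D1, 2 D2); site 4 has missing calls
    dosages = [
        [0, 0, 0, 0, 0, 0, 0, 0],
        [0, 1, 1, 2, 0, 1, 2, 2],
        [2, 2, 2, 2, 0, 0, 0, 0],
        [1, 1, 0, 0, 1, 2, 1, 0],
        [0, -1, 1, -1, 2, -1, 0, 1],
        [0, 0, 1, 0, 0, 0, 0, 1],
    ]
    return make_gm(dosages, pops=["W", "W", "W", "W", "D1", "D1", "D2", "D2"])
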