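import numpy as np
import pytest

from gradsweep.io_formats import HaplotypePanel


def random_panel(rng, n_samples=4, n_sites=12, chrom="chr1", max_pos=100_000):
    """Small random phased panel with polymorphism guaranteed per site."""
    positions = np.sort(rng.choice(np.arange(1, max_pos), size=n_sites, replace=False))
    hap = rng.integers(0, 2, size=(2 * n_samples, n_sites)).astype(np.int8)
    # force every site polymorphic so haplotype statistics are defined
    for j in range(n_sites):
        if hap[:, j].sum() == 0:
            hap[rng.integers(0, 2 * n_samples), j] = 1
        elif hap[:, j].sum() == 2 * n_samples:
            hap[rng.integers(0, 2 * n_samples), j] = 0
    return HaplotypePanel(
        chrom=chrom,
        positions=positions,
        ref_allele=np.asarray(["A"] * n_sites, dtype=object),
        alt_allele=np.asarray(["T"] * n_sites, dtype=object),
        haplotypes=hap,
        sample_ids=[f"s{i}" for i in range(n_samples)],
        breed=["B"] * n_samples,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
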