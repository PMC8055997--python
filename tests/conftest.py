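import numpy as np
import pytest

from snpdelim.genotypes import GenotypeMatrix
from snpdelim.simulate import PopModel, simulate
from snpdelim.vae import VAEEmbedder


@pytest.fixture
def tiny_matrix() -> GenotypeMatrix:
    """2 samples x 3 biallelic sites with exactly one missing entry."""
    hap = np.array(
        [
            [0, 1, 1],
            [0, -9, 1],
            [1, 0, 0],
            [1, 1, 0],
        ],
        dtype=np.int16,
    )
    return GenotypeMatrix(
        sample_ids=["P1", "P2"],
        haplotypes=hap,
        locus_of_site=["L1", "L1", "L2"],
    )


def random_matrix(rng: np.random.Generator, n=4, sites=6, with_pop=False) -> GenotypeMatrix:
    hap = rng.integers(0, 2, size=(2 * n, sites)).astype(np.int16)
    hap[rng.random((2 * n, sites)) < 0.3] = -9
    return GenotypeMatrix(
        sample_ids=[f"S{i}" for i in range(n)],
        haplotypes=hap,
        locus_of_site=[f"L{j // 2}" for j in range(sites)],
        populations=[f"pop{i % 2}" for i in range(n)] if with_pop else None,
    )


@pytest.fixture(scope="session")
def two_pop_embedding():
    """A VAE embedding of a clean two-population simulation (shared)."""
    gm, truth = simulate(
        PopModel(K_true=2, n_per_pop=10, L=400, F_per_pop=0.3, missing_rate=0.0, seed=11)
    )
    est = VAEEmbedder(epochs=300, replicates=2, random_state=0).fit(gm)
    return gm, truth, est
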