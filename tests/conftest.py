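import numpy as np
import pytest

from margin_adapt import GenotypeMatrix, GenotypeSimConfig, simulate_genotypes


@pytest.fixture(scope="session")
def study_genotypes() -> GenotypeMatrix:
    """Default synthetic study dataset: 4 populations x 42-45 diploids x 7 loci."""
    return simulate_genotypes(GenotypeSimConfig(), seed=20060601)


def random_genotype_matrix(rng: np.random.Generator,
                           n_pops: int | None = None,
                           max_n: int = 10,
                           max_loci: int = 3,
                           max_alleles: int = 4,
                           missing_rate: float = 0.1) -> GenotypeMatrix:
    """Small random genotype table for fuzzing and oracles."""
    n_pops = n_pops if n_pops is not None else int(rng.integers(2, 5))
    n_loci = int(rng.integers(1, max_loci + 1))
    sizes = rng.integers(2, max_n + 1, size=n_pops)
    n = int(sizes.sum())
    calls = rng.integers(1, max_alleles + 1, size=(n, n_loci, 2)).astype(np.int32)
    miss = rng.random((n, n_loci)) < missing_rate
    calls[miss] = 0
    pops = []
    for k, s in enumerate(sizes):
        pops.extend([f"P{k + 1}"] * int(s))
    inds = [f"{p}_{i:02d}" for i, p in enumerate(pops)]
    loci = [f"L{j + 1}" for j in range(n_loci)]
    return GenotypeMatrix(inds, loci, pops, calls)
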