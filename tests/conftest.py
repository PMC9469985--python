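import numpy as np
import pytest

from sibpop.genio import GenotypeTable
from sibpop.simulate import SimConfig, balanced_tree, simulate_hierarchical


def random_table(rng: np.random.Generator, n: int = 12, loci: int = 3, max_allele: int = 5, missing_rate: float = 0.1) -> GenotypeTable:
    """Random genotype table helper shared across test modules."""
    calls = rng.integers(1, max_allele + 1, size=(n, loci, 2))
    miss = rng.random((n, loci)) < missing_rate
    calls[miss] = 0
    return GenotypeTable(
        [f"ind{i}" for i in range(n)],
        [f"loc{j}" for j in range(loci)],
        calls,
        [f"POP{1 if i < n // 2 else 2}" for i in range(n)],
    )


@pytest.fixture(scope="session")
def two_deme_dataset():
    """Two strongly drifted demes (F = 0.25), 30 individuals each."""
    return simulate_hierarchical(SimConfig(tree=balanced_tree(1), F=0.25, samples_per_deme=30, loci=15, seed=7))


@pytest.fixture(scope="session")
def panmictic_dataset():
    """A single random-mating deme of 60 individuals."""
    return simulate_hierarchical(SimConfig(tree="deme", samples_per_deme=60, loci=15, seed=13))
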