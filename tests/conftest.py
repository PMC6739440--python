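import numpy as np
import pytest

from cubpipe.genetic_code import GeneticCode
from cubpipe.synthetic_data import SimulationConfig, simulate_ortholog_set


@pytest.fixture(scope="session")
def code() -> GeneticCode:
    return GeneticCode.standard()


@pytest.fixture(scope="session")
def small_sim():
    """A small 4-species simulated data set shared across read-only tests."""
    config = SimulationConfig(seed=11, n_species=4, n_cogs=25,
                              protein_length_mean=120,
                              gc3_targets=(0.35, 0.45, 0.55, 0.65))
    return simulate_ortholog_set(config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_counts(rng: np.random.Generator, code: GeneticCode,
                  max_codons: int = 200):
    """Random small codon-count vector (some families may be empty)."""
    import pandas as pd

    n = int(rng.integers(1, max_codons))
    codons = rng.choice(code.sense_codons, size=n)
    counts = pd.Series(0, index=list(code.sense_codons), dtype=int)
    for c in codons:
        counts[c] += 1
    return counts
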