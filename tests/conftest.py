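import numpy as np
import pytest

from selexseed import SamplePool, build_pool


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture
def small_pool():
    return SamplePool(counts={"ACG": 2, "AAA": 1}, library="SIM", cycle=1)


@pytest.fixture
def multinomial_pool(rng):
    """1e5 draws from a 100-species multinomial with uneven weights."""
    species = ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(100)]
    weights = rng.dirichlet(np.full(100, 0.3))
    draws = rng.choice(species, size=100_000, p=weights)
    return build_pool(draws, cycle=5), list(draws)
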