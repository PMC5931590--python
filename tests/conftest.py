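import numpy as np
import pytest
from hypothesis import settings

from kosig.simulate import make_toy_genome

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def toy_genome():
    return make_toy_genome(length=200_000, seed=3)


@pytest.fixture(scope="session")
def reference(toy_genome):
    return toy_genome.reference


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
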