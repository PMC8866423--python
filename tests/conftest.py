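import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bgcphylo.synthetic_data import SimParams, evolve_repertoires, simulate_tree

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_sim():
    """A 10-taxon simulation with default evolutionary rates (seed 1)."""
    params = SimParams(n_taxa=10, seed=1)
    tree = simulate_tree(params.n_taxa, params.birth_rate, seed=1)
    return evolve_repertoires(tree, params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
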