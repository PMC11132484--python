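import numpy as np
import pytest
from hypothesis import settings

import cvdabm as c

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Default synthetic parameter set (shared, treated as read-only)."""
    return c.generate_fixture_parameters(seed=1)


@pytest.fixture(scope="session")
def small_population(params):
    """A 4,000-agent population with all network layers, fixed seed."""
    pop, graph = c.generate_population(4000, params, seed=11)
    return pop, graph


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
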