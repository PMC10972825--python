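import numpy as np
import pytest

from craburden.synthetic import default_config, generate_world


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world shared by tests that only need structure."""
    cfg = default_config(seed=17, draws=100, n_locations=6)
    return generate_world(cfg)


@pytest.fixture(scope="session")
def default_world():
    """The full default world (seed 17, 1000 draws) for recovery checks."""
    return generate_world(default_config(seed=17, draws=1000))
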