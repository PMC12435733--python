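import numpy as np
import pytest

from petolag.allometry import make_environment
from petolag.lifehistory import LifespanTable


@pytest.fixture(scope="session")
def small_env():
    """The miniaturised 0.8 kg flightless lineage with constant k."""
    return make_environment(0.8, baseline_k=1e-4)


@pytest.fixture(scope="session")
def large_env():
    """The 220.7 kg 'dinosaur-like' constant large flightless lineage."""
    return make_environment(220.7, baseline_k=1e-4)


@pytest.fixture(scope="session")
def small_table(small_env):
    return LifespanTable(small_env, n_steps=3)


@pytest.fixture(scope="session")
def large_table(large_env):
    return LifespanTable(large_env, n_steps=3)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
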