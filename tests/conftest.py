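import numpy as np
import pytest

from cfmap.simulate import SimConfig, simulate_session


@pytest.fixture(scope="session")
def small_session():
    """One modest synthetic session shared by read-only tests."""
    config = SimConfig(trials_per_session=20)
    return simulate_session(config, "m00", seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
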