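import numpy as np
import pytest

from boarest.simulate import simulate_scenario


@pytest.fixture(scope="session")
def small_study():
    """One small synthetic study shared by read-only tests."""
    return simulate_scenario("small", seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
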