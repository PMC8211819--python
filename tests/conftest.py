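import numpy as np
import pytest

from rloopkit import simulate


@pytest.fixture(scope="session")
def default_sim():
    """One full synthetic dataset at the default study conditions."""
    return simulate.simulate_all(simulate.SimulationConfig(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, length, p_g=0.25):
    p = [(1 - p_g) / 3] * 3 + [p_g]
    return "".join(rng.choice(list("ACTG"), size=length, p=p))
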