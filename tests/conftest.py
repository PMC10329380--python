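import numpy as np
import pytest

from smkymo import SimParams, simulate_movie


@pytest.fixture(scope="session")
def small_movie():
    """A short, low-density simulated acquisition shared across tests."""
    params = SimParams(
        n_frames=40, fov=(48, 48), arrival_rate=0.15, seed=7
    )
    stack, truth = simulate_movie(params)
    return params, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
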