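import numpy as np
import pytest

from pathfep.system import HybridSystem
from pathfep.toys import ToyTransferSpec, make_toy_transfer


@pytest.fixture(scope="session")
def toy():
    """Default transfer toy, built once per session."""
    return make_toy_transfer(ToyTransferSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_hybrid(rng):
    """Small random hybrid system with well-separated layers."""
    n, m = 5, 8
    active = rng.normal(scale=2.0, size=(n, 3))
    env = rng.normal(scale=2.0, size=(m, 3)) + np.array([12.0, 0.0, 0.0])
    positions = np.concatenate([active.ravel(), env.ravel()])
    return HybridSystem(
        positions=positions,
        active_indices=np.arange(n),
        environment_indices=np.arange(n, n + m),
        env_charges=rng.normal(scale=0.5, size=m),
        lj_epsilon=rng.uniform(0.05, 0.3, n + m),
        lj_sigma=rng.uniform(2.5, 3.5, n + m),
    )
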