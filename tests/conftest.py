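import numpy as np
import pytest

from ictonet.model import ModelParams, WeightedNetwork


@pytest.fixture(scope="session")
def short_params():
    """Scaled-down simulation horizon used throughout the tests."""
    return ModelParams(i0=-1.0, k=10.0, sigma=6.0, dt=1e-2, n_steps=20_000, burn_in=1_000)


@pytest.fixture(scope="session")
def random_net16():
    """A fixed moderately dense 16-node network."""
    rng = np.random.default_rng(42)
    n = 16
    w = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    mask = rng.random(len(iu[0])) < 0.3
    w[iu] = np.where(mask, rng.uniform(0.25, 0.75, len(iu[0])), 0.0)
    return WeightedNetwork(w + w.T)
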