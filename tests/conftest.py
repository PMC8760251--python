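import numpy as np
import pytest

from nullspan import (decompose, make_sender_params, simulate_sender)
from nullspan.rate_network import ActivityMatrix


@pytest.fixture(scope="session")
def sender_small():
    """Smoothed sender activity, N=20, 3 s: shared by feedforward tests."""
    params = make_sender_params(20, seed=101)
    return simulate_sender(params, 3000.0)


@pytest.fixture(scope="session")
def sender_small_basis(sender_small):
    return decompose(sender_small)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_activity(rng):
    """Unstructured activity matrix, 10 x 500."""
    return ActivityMatrix(rates=rng.normal(5.0, 1.0, (10, 500)), dt=1.0)


def make_toy_activity(seed=0, t=1500):
    """Three-neuron sender with a near-flat mode spectrum.

    Singular values (1, 0.9, 0.8): all modes carry comparable variance, so
    silencing the top mode demonstrates gating without attenuation.
    """
    rng_ = np.random.default_rng(seed)
    walks = np.cumsum(rng_.normal(size=(t, 3)), axis=0)
    walks -= walks.mean(axis=0)
    v, _ = np.linalg.qr(walks)
    u, _ = np.linalg.qr(rng_.normal(size=(3, 3)))
    x = (u * np.array([1.0, 0.9, 0.8])) @ v.T
    return ActivityMatrix(rates=x, dt=1.0)
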