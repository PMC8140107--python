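import numpy as np
import pytest

from neuropm.io import Connectome
from neuropm.synthetic import generate_connectome


@pytest.fixture(scope="session")
def small_connectome() -> Connectome:
    """Connected 10-node weighted graph scaled for propagating dynamics."""
    conn = generate_connectome(10, density=0.4, seed=3)
    conn.weights *= 3.0 / conn.weights.sum(axis=1).mean()
    return conn


@pytest.fixture(scope="session")
def mcm_connectome() -> Connectome:
    """8-node graph with unit mean row-sum for causal-model tests."""
    conn = generate_connectome(8, density=0.5, seed=11)
    conn.weights /= conn.weights.sum(axis=1).mean()
    return conn


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
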