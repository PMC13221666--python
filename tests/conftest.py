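import logging

import numpy as np
import pytest

from rhlvggm.core import ObservedData
from rhlvggm.simulate import SimulationConfig, simulate

logging.getLogger("rhlvggm").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_truth():
    """A modest reference-style dataset reused by fit-level tests."""
    cfg = SimulationConfig(p=20, r=3, n=600, pi0=0.04, mu_scale=3.0, seed=7)
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_data(small_truth):
    return ObservedData(small_truth.X)


def random_pd(rng, p, scale=1.0):
    A = rng.normal(size=(p, p))
    return scale * (A @ A.T / p + np.eye(p))
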