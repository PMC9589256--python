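import numpy as np
import pytest

from pshima import RunConfig, SimulationConfig, generate_dataset
from pshima.propensity import fit_propensity


@pytest.fixture(scope="session")
def mode1_small():
    """One mode-1 study at the benchmark's smaller setting."""
    return generate_dataset(SimulationConfig(n=300, p=1000, mode=1, seed=1))


@pytest.fixture(scope="session")
def mode1_small_ps(mode1_small):
    return fit_propensity(mode1_small.X, mode1_small.Z)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_regression(rng):
    """Small dense regression problem with known planted structure."""
    n = 40
    X = (rng.random(n) < 0.5).astype(float)
    S = rng.uniform(0.2, 0.8, n)
    M = rng.standard_normal((n, 3))
    Y = 1.0 + 0.5 * X + 2.0 * M[:, 0] - 1.0 * M[:, 2] + 0.3 * S + 0.1 * rng.standard_normal(n)
    return X, S, M, Y
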