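import numpy as np
import pytest

from coxradius import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-interaction cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(n_patients=60, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_survival(rng, n, p=2, tie_frac=0.0, beta_scale=0.7):
    """Random Cox-type dataset used by oracle-agreement tests."""
    X = rng.normal(size=(n, p))
    beta = rng.normal(scale=beta_scale, size=p)
    t = rng.exponential(np.exp(-(X @ beta)))
    if tie_frac > 0:
        t = np.round(t, 1) + 0.01
    c = rng.exponential(2.0 * np.median(t), size=n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return X, time, event
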