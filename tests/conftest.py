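import numpy as np
import pytest

from polydif.simulate import simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170912)


@pytest.fixture(scope="session")
def small_study_data():
    """One replication of the smallest design cell (50 clusters x 5, DIF 0.4)."""
    return simulate_dataset(
        50, 5, 0.05, 0.4, "within", rng=np.random.default_rng(11)
    )


@pytest.fixture(scope="session")
def ordinal_fixture():
    """60 observations, 3 categories, 1 predictor, from a known model."""
    r = np.random.default_rng(42)
    x = r.normal(size=60)
    eta = 0.7 * x
    from scipy.special import expit

    cum = expit(np.array([-0.5, 0.9])[None, :] - eta[:, None])
    cum = np.hstack([np.zeros((60, 1)), cum, np.ones((60, 1))])
    y = np.array([r.choice(3, p=p) for p in np.diff(cum, axis=1)])
    return y, x[:, None]


@pytest.fixture(scope="session")
def mixed_fixture():
    """10 clusters x 6 persons, 3 categories, 1 predictor, true sigma_u2 = 0.49."""
    r = np.random.default_rng(3)
    J, m = 10, 6
    cl = np.repeat(np.arange(J), m)
    u = r.normal(0, 0.7, J)
    x = r.normal(size=J * m)
    eta = 0.8 * x + u[cl]
    from scipy.special import expit

    cum = expit(np.array([-0.5, 0.8])[None, :] - eta[:, None])
    cum = np.hstack([np.zeros((J * m, 1)), cum, np.ones((J * m, 1))])
    y = np.array([r.choice(3, p=p) for p in np.diff(cum, axis=1)])
    return y, x[:, None], cl
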