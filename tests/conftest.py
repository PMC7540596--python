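import numpy as np
import pytest

from fairreg.synthetic_data import generate_spending_population


def random_instance(seed, n=None, p=None, group_effect=3.0, noise=1.0):
    """Small random risk-adjustment instance: Gaussian covariates plus a
    latent group effect that the design cannot fully explain, so the group
    is undercompensated under OLS."""
    rng = np.random.default_rng(seed)
    n = n if n is not None else int(rng.integers(60, 200))
    p = p if p is not None else int(rng.integers(2, 9))
    X = rng.standard_normal((n, p))
    # one binary column keeps the design claims-like
    X[:, 0] = (rng.random(n) < 0.3).astype(float)
    a = (rng.random(n) < 0.25).astype(int)
    if a.sum() < 2:
        a[:2] = 1
    if a.sum() > n - 2:
        a[:2] = 0
    beta = rng.standard_normal(p)
    y = X @ beta + group_effect * a + noise * rng.standard_normal(n)
    return X, y, a


@pytest.fixture(scope="session")
def spending_fixture():
    """Mid-size claims-like population shared across estimator/CV tests."""
    return generate_spending_population(n=6000, seed=0)


@pytest.fixture(scope="session")
def spending_fixture_10k():
    """The evaluation-scale fixture used by the trade-off and ordering
    checks."""
    return generate_spending_population(n=10_000, seed=0)
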