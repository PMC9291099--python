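import numpy as np
import pandas as pd
import pytest

from condsem import fixture_true_model, simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210906)


@pytest.fixture(scope="session")
def factor_data(rng):
    """One-factor, three-indicator Gaussian data (n = 2000)."""
    n = 2000
    f = rng.normal(size=n)
    lam = np.array([1.0, 0.8, 1.3])
    eps = rng.normal(size=(n, 3)) * np.array([0.7, 0.6, 0.9])
    return pd.DataFrame(np.outer(f, lam) + eps, columns=["x1", "x2", "x3"])


@pytest.fixture(scope="session")
def regression_data(rng):
    """Two correlated predictors and a linear response (n = 600)."""
    n = 600
    x = rng.multivariate_normal([0, 0], [[1.0, 0.4], [0.4, 2.0]], size=n)
    y = 0.7 * x[:, 0] - 0.3 * x[:, 1] + rng.normal(scale=0.8, size=n)
    return pd.DataFrame(np.column_stack([x, y]), columns=["x1", "x2", "y"])


@pytest.fixture(scope="session")
def condition_data():
    """One simulated dataset from the condition fixture (n = 1500)."""
    return simulate_dataset(fixture_true_model("condition"), 1500, seed=42)
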