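import numpy as np
import pytest

from simplexmm.data import LongitudinalData
from simplexmm.simplex import default_expected_d2_table


@pytest.fixture(scope="session")
def d2tab():
    """Shared expected-curvature spline table (built once)."""
    return default_expected_d2_table()


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def tiny_data(rng):
    """Small balanced dataset (8 subjects x 3 visits, p=2, q=2)."""
    n, n_i = 8, 3
    N = n * n_i
    t = np.tile(0.2 * np.arange(n_i), n)
    X = np.column_stack([np.ones(N), rng.choice([-1.0, 1.0], N), rng.standard_normal(N)])
    Z = np.column_stack([np.ones(N), t])
    subject = np.repeat(np.arange(n), n_i)
    b = rng.normal(0.0, 0.5, size=(n, 2))
    eta = X @ np.array([-0.3, 0.2, 0.4]) + np.einsum("nq,nq->n", Z, b[subject])
    y = 1.0 / (1.0 + np.exp(-eta)) * 0.8 + 0.1  # deterministic, inside (0,1)
    return LongitudinalData(y=y, X=X, Z=Z, subject=subject, time=t)
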