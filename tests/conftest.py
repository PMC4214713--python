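import numpy as np
import pytest

from minedesign import DataSet, TruthConfig, fit_posterior

#: the ten nonzero coefficients of the standard 1000-coefficient benchmark
BENCH_NONZERO = [11.0, -36.0, -26.0, 9.0, 33.0, -50.0, -45.0, 15.0, 3.0, 17.0]


def small_truth(p=50, sigma=0.01, d=5, n_experiments=15, seed=5, b=None):
    """Small sparse-truth configuration carrying the benchmark's nonzero values."""
    beta = np.zeros(p)
    beta[:10] = BENCH_NONZERO
    return TruthConfig(
        p=p,
        beta_true=beta,
        sigma=sigma,
        b=b if b is not None else 1.0 / 50.0**2,
        d=d,
        n_experiments=n_experiments,
        pilot_size=10,
        alpha=0.01,
        seed=seed,
    )


def random_posterior(rng, p=None, n=None, sigma=None, b=None):
    """A posterior fitted to random data; dimensions drawn if not given."""
    p = p if p is not None else int(rng.integers(5, 31))
    n = n if n is not None else int(rng.integers(0, 2 * p))
    sigma = sigma if sigma is not None else float(rng.uniform(0.05, 2.0))
    b = b if b is not None else float(rng.uniform(1e-4, 1.0))
    X = rng.standard_normal((n, p))
    y = rng.standard_normal(n)
    return fit_posterior(DataSet(X, y), sigma, b)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
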