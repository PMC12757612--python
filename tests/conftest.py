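import numpy as np
import pytest

from fsnblr.model_core import (
    Dataset,
    OscillationOrders,
    ParameterVector,
    build_design,
    log_likelihood,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_instance(rng, n=30, K=(2, 1), x_scale=2.0, theta_scale=0.5):
    """A random (y, design, theta) triple for calculus/fit checks."""
    K = OscillationOrders(K)
    X = rng.uniform(-x_scale, x_scale, size=(n, K.p))
    design = build_design(X, K)
    theta = rng.normal(scale=theta_scale, size=design.m)
    y = rng.binomial(1, 0.5, size=n).astype(float)
    return y, design, theta


def fd_gradient(y, design, theta, h=1e-6):
    """Central finite differences of the log-likelihood."""
    theta = np.asarray(theta, dtype=float)
    out = np.empty_like(theta)
    for i in range(theta.size):
        up, dn = theta.copy(), theta.copy()
        up[i] += h
        dn[i] -= h
        out[i] = (log_likelihood(y, design, up) - log_likelihood(y, design, dn)) / (2 * h)
    return out


def fd_hessian(y, design, theta, h=1e-4):
    """Second-order central differences of the log-likelihood."""
    theta = np.asarray(theta, dtype=float)
    m = theta.size
    out = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            pp, pm, mp, mm = (theta.copy() for _ in range(4))
            np.add.at(pp, [i, j], h)     # handles i == j (step 2h)
            np.add.at(mm, [i, j], -h)
            pm[i] += h
            pm[j] -= h
            mp[i] -= h
            mp[j] += h
            val = (
                log_likelihood(y, design, pp)
                - log_likelihood(y, design, pm)
                - log_likelihood(y, design, mp)
                + log_likelihood(y, design, mm)
            ) / (4 * h * h)
            out[i, j] = out[j, i] = val
    return out


@pytest.fixture
def small_dataset(rng):
    """A 60-row, 2-predictor dataset with both classes present."""
    X = rng.uniform(0.0, 10.0, size=(60, 2))
    eta = 0.5 - 0.3 * X[:, 0] + 0.2 * X[:, 1]
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return Dataset(y, X)


@pytest.fixture
def balanced_dataset(rng):
    """Exactly half ones, for closed-form intercept checks."""
    n = 40
    y = np.array([0.0, 1.0] * (n // 2))
    X = rng.normal(size=(n, 2))
    return Dataset(y, X)


def theta_from_blocks(a0, b, a):
    return ParameterVector(a0, b, a)
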