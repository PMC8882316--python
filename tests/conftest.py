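import numpy as np
import pytest

from bayesenrich.posterior import PosteriorDraws, SubsetArmCounts


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def balanced_counts():
    """Identical counts in both arms of both subsets (exchangeable arms)."""
    return SubsetArmCounts(
        ("A", "B"),
        events=np.array([[30, 30], [30, 30]]),
        totals=np.array([[100, 100], [100, 100]]),
    )


def make_draws(p, theta_global=None, subsets=None):
    """Assemble a PosteriorDraws from an explicit p array (n, 2, K)."""
    p = np.asarray(p, dtype=float)
    theta = p[:, 1, :] / p[:, 0, :]
    if theta_global is None:
        theta_global = theta.mean(axis=1)
    if subsets is None:
        subsets = tuple("ABCDEFG"[: p.shape[2]])
    return PosteriorDraws(
        subsets=tuple(subsets),
        p=p,
        theta=theta,
        log_theta=np.log(theta),
        theta_global=np.asarray(theta_global, dtype=float),
        n_draws=p.shape[0],
        seed=None,
    )


def draws_from_theta(theta, theta_global=None, subsets=None):
    """Assemble a PosteriorDraws directly from theta draws (n, K)."""
    theta = np.asarray(theta, dtype=float)
    n, K = theta.shape
    p = np.empty((n, 2, K))
    p[:, 0, :] = 0.4
    p[:, 1, :] = 0.4 * theta
    return make_draws(p, theta_global=theta_global, subsets=subsets)
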