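import numpy as np
import pytest

from sniffsearch.arhmm import ARHMMParams
from sniffsearch.synthetic import SessionConfig, gen_sniff_trace, simulate_session


@pytest.fixture(scope="session")
def toy_arhmm():
    """Tiny S=2, d=1 model with a short trajectory, small enough for
    exhaustive enumeration over all label sequences."""
    params = ARHMMParams(
        pi=np.array([[0.8, 0.2], [0.3, 0.7]]),
        init=np.array([0.5, 0.5]),
        A=np.array([[[0.5]], [[0.9]]]),
        b=np.array([[1.0], [-0.5]]),
        Q=np.array([[[0.3]], [[0.3]]]),
    )
    rng = np.random.default_rng(0)
    x = rng.normal(0.0, 1.0, (8, 1)).cumsum(axis=0) * 0.5
    return params, x


@pytest.fixture(scope="session")
def steady_sniffs():
    """A clean 5 Hz sniff trace with planted events."""
    return gen_sniff_trace(5.0, duration=30.0, seed=11, jitter=0.02)


@pytest.fixture(scope="session")
def small_session():
    cfg = SessionConfig(n_trials=10, make_traces=False)
    return simulate_session(cfg, seed=5)


def enumerate_posterior(params, x):
    """Brute-force posterior state marginals and marginal likelihood by
    summing over every label sequence (oracle for the samplers)."""
    from itertools import product

    from sniffsearch.arhmm import emission_loglik

    T = x.shape[0]
    S = params.S
    logb = emission_loglik(params, x)
    logpi = np.log(params.pi)
    weights = []
    for zs in product(range(S), repeat=T):
        z = np.array(zs)
        lw = (np.log(params.init[z[0]]) + logpi[z[:-1], z[1:]].sum()
              + logb[np.arange(1, T), z[1:]].sum())
        weights.append((z, lw))
    m = max(lw for _, lw in weights)
    Z = sum(np.exp(lw - m) for _, lw in weights)
    post = np.zeros((T, S))
    for z, lw in weights:
        post[np.arange(T), z] += np.exp(lw - m) / Z
    return post, m + np.log(Z)
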