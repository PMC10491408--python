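import itertools

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

import switchssm as sw
from switchssm.ssm import gaussian_condition, joint_gaussian_oracle


def random_ssm(rng, d=1, p=1, stable=0.6):
    """A random well-conditioned Gaussian SSM."""
    F = rng.standard_normal((d, d)) * stable / np.sqrt(d)
    A = rng.standard_normal((d, d))
    Q = A @ A.T + 0.3 * np.eye(d)
    B = rng.standard_normal((d, d))
    Q0 = B @ B.T + 0.3 * np.eye(d)
    G = rng.standard_normal((p, d))
    mu = rng.standard_normal(d)
    return sw.GaussianSSM(mu, Q0, F, Q, G)


def random_R(rng, p=1):
    return np.diag(rng.uniform(0.2, 1.0, p))


def random_chain(rng, M):
    rho = rng.dirichlet(np.ones(M))
    phi = rng.dirichlet(np.ones(M), size=M).T  # columns sum to one
    return sw.MarkovChainParams(rho, phi)


def enumerate_chain_posterior(g, rho, phi):
    """Brute-force posterior of s_0..s_T given per-time log evidence g (T, M)."""
    T, M = g.shape
    tot = []
    paths = list(itertools.product(range(M), repeat=T + 1))
    for path in paths:
        lp = np.log(rho[path[0]])
        for t in range(1, T + 1):
            lp += np.log(phi[path[t], path[t - 1]]) + g[t - 1, path[t]]
        tot.append(lp)
    tot = np.asarray(tot)
    logZ = logsumexp(tot)
    w = np.exp(tot - logZ)
    margs = np.zeros((T + 1, M))
    pair = np.zeros((T, M, M))
    for wk, path in zip(w, paths):
        for t in range(T + 1):
            margs[t, path[t]] += wk
        for t in range(1, T + 1):
            pair[t - 1, path[t], path[t - 1]] += wk
    best = paths[int(np.argmax(tot))]
    return logZ, margs, pair, best


def exact_switching_loglik(model, y):
    """log p(y) of a parallel-state switching model by path enumeration.

    Given the switch path, observations decompose per candidate: the ones a
    model emits form a marginal Gaussian under that model's prior (with R on
    the diagonal of the emitted block).
    """
    T = y.shape[0]
    M = model.M
    joints = []
    for ssm in model.ssms:
        mean, cov, xi, yi = joint_gaussian_oracle(ssm, model.R, T)
        n0 = (T + 1) * ssm.d
        joints.append((mean[n0:], cov[n0:, n0:]))
    rho, phi = model.chain.rho, model.chain.phi
    lls = []
    for path in itertools.product(range(M), repeat=T + 1):
        lp = np.log(rho[path[0]])
        for t in range(1, T + 1):
            lp += np.log(phi[path[t], path[t - 1]])
        for m in range(M):
            idx = [t - 1 for t in range(1, T + 1) if path[t] == m]
            if idx:
                mu_, cov_ = joints[m]
                lp += multivariate_normal(mu_[idx], cov_[np.ix_(idx, idx)]).logpdf(y[idx, 0])
        lls.append(lp)
    return logsumexp(lls)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def ar1_model():
    return sw.make_ar1_switching()


__all__ = [
    "random_ssm", "random_R", "random_chain",
    "enumerate_chain_posterior", "exact_switching_loglik",
    "gaussian_condition", "joint_gaussian_oracle",
]
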