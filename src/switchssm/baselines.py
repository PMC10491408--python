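"""Classical switching-inference comparators.

All baselines return filtered (or per-time) model probabilities; none of them
uses the variational machinery.  Conventions match the rest of the package:
phi[m, n] = P(s_t = m | s_{t-1} = n), observations start at t = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .model import SwitchingModel
from .ssm import as_observations, kalman_filter


@dataclass
class BaselinePosterior:
    """Per-time model probabilities (rows sum to 1) and hard labels."""

    probs: np.ndarray
    labels: np.ndarray


def _labels(probs):
    return probs.argmax(axis=1)


def _reversed_ssm(ssm):
    """Time-reversed stationary model: F_rev = S F' S^-1 with S the stationary
    state covariance; near-unstable dynamics are radius-clamped for the
    reversal only."""
    from scipy.linalg import solve_discrete_lyapunov

    F = ssm.F
    rad = np.abs(np.linalg.eigvals(F)).max()
    if rad >= 0.999:
        F = F * (0.999 / rad)
    S = solve_discrete_lyapunov(F, ssm.Q)
    Fr = S @ F.T @ np.linalg.inv(S)
    Qr = S - Fr @ S @ Fr.T
    Qr = 0.5 * (Qr + Qr.T) + 1e-10 * np.eye(ssm.d)
    from .ssm import GaussianSSM

    return GaussianSSM(np.zeros(ssm.d), S, Fr, Qr, ssm.G)


def static_switching(model: SwitchingModel, y) -> BaselinePosterior:
    """Per-time Bayes rule on per-model predictive densities, HMM ignored.

    The switch state is treated as independent across time: the probability of
    model m at time t is proportional to prior_m times the evidence that model
    m assigns to y_t.  The evidence combines the forward one-step predictive
    density p(y_t | y_{1:t-1}, m) with its time-reversed counterpart
    p(y_t | y_{t+1:T}, m) (a backward filter under the stationary reversal of
    each candidate), so each per-time decision sees both past and future
    context while no transition structure is used.
    """
    obs = as_observations(y)
    with np.errstate(divide="ignore"):
        logprior = np.log(model.chain.rho)
    cols = []
    for ssm in model.ssms:
        fwd = kalman_filter(ssm, obs, model.R).loglik_steps
        bwd = kalman_filter(_reversed_ssm(ssm), obs.y[::-1].copy(), model.R).loglik_steps[::-1]
        cols.append(fwd + bwd)
    logp = np.column_stack(cols) + logprior
    logp -= logsumexp(logp, axis=1, keepdims=True)
    probs = np.exp(logp)
    return BaselinePosterior(probs, _labels(probs))


def _union_layout(model: SwitchingModel):
    """(union dim, per-model index arrays); identity when dims are equal."""
    if len(set(model.dims)) == 1 and model.state_blocks is None:
        d = model.dims[0]
        return d, [np.arange(d) for _ in model.ssms]
    if model.state_blocks is None:
        raise ValueError(
            "candidate models differ in state dimension; the model needs "
            "state_blocks mapping each candidate into a union state"
        )
    D = int(max(b.max() for b in model.state_blocks)) + 1
    return D, model.state_blocks


def imm(model: SwitchingModel, y) -> BaselinePosterior:
    """Interacting-multiple-models filter (moment-matched Gaussian mixing).

    Candidates of unequal state dimension are mixed on the zero-padded union
    state defined by model.state_blocks.
    """
    obs = as_observations(y)
    T, p = obs.T, obs.p
    M = model.M
    phi = model.chain.phi
    D, blocks = _union_layout(model)
    Rm = model.R

    xs = [ssm.mu.copy() for ssm in model.ssms]
    Ps = [ssm.Q0.copy() for ssm in model.ssms]
    mu_prob = model.chain.rho.copy()
    probs = np.empty((T, M))
    for t in range(T):
        mu_pred = phi @ mu_prob
        mu_pred = np.maximum(mu_pred, 1e-300)
        # mixing on the union state
        ux = np.zeros((M, D))
        uP = np.zeros((M, D, D))
        for n in range(M):
            idx = blocks[n]
            ux[n][idx] = xs[n]
            uP[n][np.ix_(idx, idx)] = Ps[n]
        loglik = np.empty(M)
        new_xs, new_Ps = [], []
        for m in range(M):
            w = phi[m] * mu_prob / mu_pred[m]
            x0 = np.einsum("n,nd->d", w, ux)
            P0 = np.zeros((D, D))
            for n in range(M):
                dev = ux[n] - x0
                P0 += w[n] * (uP[n] + np.outer(dev, dev))
            idx = blocks[m]
            xm = x0[idx]
            Pm = P0[np.ix_(idx, idx)]
            ssm = model.ssms[m]
            xm = ssm.F @ xm
            Pm = ssm.F @ Pm @ ssm.F.T + ssm.Q
            G = ssm.G
            S = G @ Pm @ G.T + Rm
            innov = obs.y[t] - G @ xm
            sol = np.linalg.solve(S, innov)
            sgn, ldS = np.linalg.slogdet(S)
            loglik[m] = -0.5 * (p * np.log(2 * np.pi) + ldS + innov @ sol)
            K = np.linalg.solve(S, G @ Pm).T
            new_xs.append(xm + K @ innov)
            Pm = Pm - K @ (G @ Pm)
            new_Ps.append(0.5 * (Pm + Pm.T))
        logmu = np.log(mu_pred) + loglik
        logmu -= logsumexp(logmu)
        mu_prob = np.exp(logmu)
        xs, Ps = new_xs, new_Ps
        probs[t] = mu_prob
    return BaselinePosterior(probs, _labels(probs))


def shumway_stoffer_merge(model: SwitchingModel, y) -> BaselinePosterior:
    """Probability-weighted measurement merging for models sharing dynamics.

    Valid when the candidates share (F, Q, mu, Q0) on a common (union) state
    and only the observation matrix switches.  A single Gaussian state is
    filtered; at each step the per-model updates are merged with weights given
    by Markov-propagated filtered model probabilities.
    """
    obs = as_observations(y)
    T, p = obs.T, obs.p
    M = model.M
    D, blocks = _union_layout(model)
    # shared dynamics live on the union state of the largest candidate
    lead = int(np.argmax(model.dims))
    if model.dims[lead] != D:
        raise ValueError("one candidate must span the full union state")
    F, Q = model.ssms[lead].F, model.ssms[lead].Q
    mu0, Q0 = model.ssms[lead].mu, model.ssms[lead].Q0
    for m, ssm in enumerate(model.ssms):
        idx = blocks[m]
        if not (np.allclose(ssm.F, F[np.ix_(idx, idx)]) and np.allclose(ssm.Q, Q[np.ix_(idx, idx)])):
            raise ValueError("candidates must share dynamics; only G may switch")
    Gs = np.zeros((M, p, D))
    for m, ssm in enumerate(model.ssms):
        Gs[m][:, blocks[m]] = ssm.G
    phi = model.chain.phi
    Rm = model.R

    x, P = mu0.copy(), Q0.copy()
    pi = model.chain.rho.copy()
    probs = np.empty((T, M))
    for t in range(T):
        x = F @ x
        P = F @ P @ F.T + Q
        pi_pred = np.maximum(phi @ pi, 1e-300)
        loglik = np.empty(M)
        upd = []
        for m in range(M):
            G = Gs[m]
            S = G @ P @ G.T + Rm
            innov = obs.y[t] - G @ x
            sol = np.linalg.solve(S, innov)
            sgn, ldS = np.linalg.slogdet(S)
            loglik[m] = -0.5 * (p * np.log(2 * np.pi) + ldS + innov @ sol)
            K = np.linalg.solve(S, G @ P).T
            xm = x + K @ innov
            Pm = P - K @ (G @ P)
            upd.append((xm, 0.5 * (Pm + Pm.T)))
        logpi = np.log(pi_pred) + loglik
        logpi -= logsumexp(logpi)
        pi = np.exp(logpi)
        x = sum(pi[m] * upd[m][0] for m in range(M))
        P = np.zeros((D, D))
        for m in range(M):
            dev = upd[m][0] - x
            P += pi[m] * (upd[m][1] + np.outer(dev, dev))
        probs[t] = pi
    return BaselinePosterior(probs, _labels(probs))


def random_segmentation(T: int, M: int, seed) -> np.ndarray:
    """IID uniform labels in 0..M-1 (Bernoulli process for M = 2)."""
    rng = np.random.default_rng(seed)
    if M == 1:
        return np.zeros(T, dtype=int)
    return rng.integers(0, M, size=T)
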