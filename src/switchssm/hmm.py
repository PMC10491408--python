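"""Discrete-state machinery: log-domain forward-backward and Viterbi.

Convention: phi[m, n] = P(s_t = m | s_{t-1} = n), i.e. columns index the
source state and sum to one.  The initial state s_0 carries no emission; the
first emission is at t = 1 after one transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._core import fb_core, viterbi_core


class DegenerateEvidenceError(ValueError):
    """All states vetoed (zero posterior mass) at some time point."""


@dataclass
class MarkovChainParams:
    """Initial probabilities rho (M,) and column-stochastic transition matrix phi (M, M)."""

    rho: np.ndarray
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=np.float64)
        self.phi = np.atleast_2d(np.asarray(self.phi, dtype=np.float64))
        M = self.rho.shape[0]
        if self.phi.shape != (M, M):
            raise ValueError(f"phi must be {M}x{M}")
        if (self.rho < 0).any() or (self.phi < 0).any():
            raise ValueError("probabilities must be non-negative")
        if not np.isclose(self.rho.sum(), 1.0, atol=1e-8):
            raise ValueError("rho must sum to 1")
        if not np.allclose(self.phi.sum(axis=0), 1.0, atol=1e-8):
            raise ValueError("columns of phi must sum to 1 (phi[m, n] = P(m | n))")

    @property
    def M(self) -> int:
        return self.rho.shape[0]

    def log(self):
        with np.errstate(divide="ignore"):
            return np.log(self.rho), np.log(self.phi)


@dataclass
class MarkovPosterior:
    """Posterior of the switching chain given per-time log-evidence."""

    h: np.ndarray            # (T, M) marginals p_{t|T}(m), t = 1..T
    p0: np.ndarray           # (M,) marginal of the emission-free s_0
    pairwise: np.ndarray     # (T, M, M) p_{t,t-1|T}(m, n), t = 1..T
    log_alpha: np.ndarray    # (T+1, M) forward messages, t = 0..T
    log_beta: np.ndarray     # (T+1, M) backward messages
    logZ: float
    log_evidence: np.ndarray  # the (T, M) log-evidence g this posterior was built from


def forward_backward(g: np.ndarray, chain: MarkovChainParams) -> MarkovPosterior:
    """HMM smoothing with emission log-probabilities g (T, M).

    -inf entries veto a state at a time point; if all states are vetoed at
    some time a DegenerateEvidenceError is raised.
    """
    g = np.ascontiguousarray(np.asarray(g, dtype=np.float64))
    if g.ndim != 2 or g.shape[1] != chain.M:
        raise ValueError(f"g must be (T, {chain.M})")
    if np.isnan(g).any() or (g == np.inf).any():
        raise ValueError("g must be finite or -inf")
    logrho, logphi = chain.log()
    loga, logb, logZ = fb_core(g, logrho, logphi)
    if not np.isfinite(logZ):
        raise DegenerateEvidenceError("all states vetoed; evidence has no support")
    logpost = loga + logb - logZ
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)
    # pairwise posteriors p(s_t = m, s_{t-1} = n | y)
    T = g.shape[0]
    lp = (
        loga[:-1, None, :]                # alpha_{t-1}(n)
        + logphi[None, :, :]              # phi[m, n]
        + g[:, :, None]                   # g_t(m)
        + logb[1:, :, None]               # beta_t(m)
        - logZ
    )
    pairwise = np.exp(lp)
    pairwise /= pairwise.sum(axis=(1, 2), keepdims=True)
    return MarkovPosterior(
        h=post[1:], p0=post[0], pairwise=pairwise,
        log_alpha=loga, log_beta=logb, logZ=float(logZ), log_evidence=g,
    )


def viterbi(g: np.ndarray, chain: MarkovChainParams) -> np.ndarray:
    """Most probable joint path s_1..s_T (0-based labels) under the same conventions."""
    g = np.ascontiguousarray(np.asarray(g, dtype=np.float64))
    if g.ndim != 2 or g.shape[1] != chain.M:
        raise ValueError(f"g must be (T, {chain.M})")
    logrho, logphi = chain.log()
    path = viterbi_core(g, logrho, logphi)
    # a -inf best score means every path is vetoed
    loga, logb, logZ = fb_core(g, logrho, logphi)
    if not np.isfinite(logZ):
        raise DegenerateEvidenceError("all states vetoed; evidence has no support")
    return path
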