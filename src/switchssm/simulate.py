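"""Generative simulators for switching state-space models."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import SwitchingModel


@dataclass
class SimulationOutput:
    """Simulated observations, true switch path and hidden trajectories."""

    y: np.ndarray             # (T, p)
    s: np.ndarray             # (T,) switch labels 0..M-1 for t = 1..T
    s0: int                   # initial switch state (no emission)
    x: list                   # per-model (or union) hidden state trajectories
    seed: Optional[int] = None


def _sample_chain(chain, T, rng):
    s = np.empty(T + 1, dtype=int)
    s[0] = rng.choice(chain.M, p=chain.rho)
    for t in range(1, T + 1):
        s[t] = rng.choice(chain.M, p=chain.phi[:, s[t - 1]])
    return s


def simulate(model: SwitchingModel, T: int, seed=None) -> SimulationOutput:
    """Sample from the parallel-state generative model.

    Every candidate's hidden state evolves independently for all t; the chain
    selects which candidate emits: y_t = G^(s_t) x_t^(s_t) + v_t.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    s = _sample_chain(model.chain, T, rng)
    p = model.p
    Lr = np.linalg.cholesky(model.R)
    xs = []
    for ssm in model.ssms:
        d = ssm.d
        x = np.empty((T + 1, d))
        x[0] = ssm.mu + np.linalg.cholesky(ssm.Q0) @ rng.standard_normal(d)
        Lq = np.linalg.cholesky(ssm.Q)
        for t in range(1, T + 1):
            x[t] = ssm.F @ x[t - 1] + Lq @ rng.standard_normal(d)
        xs.append(x)
    y = np.empty((T, p))
    for t in range(1, T + 1):
        m = s[t]
        y[t - 1] = model.ssms[m].G @ xs[m][t] + Lr @ rng.standard_normal(p)
    return SimulationOutput(y=y, s=s[1:], s0=int(s[0]), x=xs, seed=seed)


def simulate_shared_state(
    model: SwitchingModel, T: int, seed=None, F_by_state=None
) -> SimulationOutput:
    """Sample a single hidden state whose transition matrix switches.

    Used for the coupled bivariate study: x_t = F^(s_t) x_{t-1} + w_t with a
    common state vector, so switches alter the dynamics without restarting
    the trajectory.  All candidates must share (Q, mu, Q0, G).
    """
    rng = np.random.default_rng(seed)
    s = _sample_chain(model.chain, T, rng)
    ref = model.ssms[0]
    Fs = F_by_state if F_by_state is not None else [m.F for m in model.ssms]
    d, p = ref.d, ref.p
    Lq = np.linalg.cholesky(ref.Q)
    Lr = np.linalg.cholesky(model.R)
    x = np.empty((T + 1, d))
    x[0] = ref.mu + np.linalg.cholesky(ref.Q0) @ rng.standard_normal(d)
    y = np.empty((T, p))
    for t in range(1, T + 1):
        x[t] = Fs[s[t]] @ x[t - 1] + Lq @ rng.standard_normal(d)
        y[t - 1] = ref.G @ x[t] + Lr @ rng.standard_normal(p)
    return SimulationOutput(y=y, s=s[1:], s0=int(s[0]), x=[x], seed=seed)


def simulate_union_oscillators(
    specs, subsets, chain, R, T: int, seed=None
) -> SimulationOutput:
    """Sample continuously-evolving oscillators observed through a switching subset.

    The n oscillators evolve for all t on a shared union state; the chain
    selects which subset of real parts is summed into the observation.  Used
    by the nested-oscillator study, where candidate k corresponds to
    ``subsets[k]``.
    """
    rng = np.random.default_rng(seed)
    from .em import rotation

    n = len(specs)
    s = _sample_chain(chain, T, rng)
    x = np.empty((T + 1, 2 * n))
    for j, sp in enumerate(specs):
        x[0, 2 * j: 2 * j + 2] = np.sqrt(sp.sigma2) * rng.standard_normal(2)
    Fs = [rotation(sp.a, sp.omega) for sp in specs]
    R = np.atleast_2d(np.asarray(R, float))
    Lr = np.linalg.cholesky(R)
    y = np.empty((T, 1))
    for t in range(1, T + 1):
        for j, sp in enumerate(specs):
            sl = slice(2 * j, 2 * j + 2)
            x[t, sl] = Fs[j] @ x[t - 1, sl] + np.sqrt(sp.sigma2) * rng.standard_normal(2)
        sub = subsets[s[t]]
        y[t - 1, 0] = sum(x[t, 2 * j] for j in sub) + Lr[0, 0] * rng.standard_normal()
    return SimulationOutput(y=y, s=s[1:], s0=int(s[0]), x=[x], seed=seed)
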