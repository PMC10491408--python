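"""Structured variational E-step for switching state-space models.

The approximate posterior factorizes over the switching chain and the M
Gaussian state sequences; the two factors communicate through the per-time,
per-model variational log-evidence g_t(m) and responsibility h_t(m).  A
fixed-point cycle alternates (1) forward-backward on g, (2) h from the chain
marginals, (3) per-model Kalman/RTS smoothing with effective observation
noise R / h_t, (4) g from the smoothed moments.  Each half-update is a
coordinate ascent step on the negative variational free energy F(q, theta),
a lower bound on log p(y | theta).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .hmm import MarkovChainParams, MarkovPosterior, forward_backward
from .model import SwitchingModel
from .ssm import (
    FilterResult,
    SmootherResult,
    as_observations,
    interpolated_log_density,
    kalman_filter,
    rts_smooth,
)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class AnnealingSchedule:
    """Deterministic-annealing temperatures T_0, (T_0+1)/2, ... toward 1."""

    T0: float = 100.0
    n_steps: int = 12

    def __post_init__(self) -> None:
        if self.T0 < 1:
            raise ValueError("initial temperature must be >= 1")

    def temperatures(self) -> np.ndarray:
        temps = np.empty(self.n_steps)
        t = self.T0
        for i in range(self.n_steps):
            temps[i] = t
            t = 0.5 * (t + 1.0)
        return temps


@dataclass
class EStepConfig:
    """Controls for the fixed-point iterations.

    init_mode is one of {"interpolated", "annealed", "given_h", "given_g"}.
    center_evidence None means: centre the interpolated-density columns iff
    the candidate models differ in state dimension (nested candidates).
    """

    init_mode: str = "interpolated"
    center_evidence: Optional[bool] = None
    max_iter: int = 50
    h_tol: float = 1e-6
    f_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.init_mode not in ("interpolated", "annealed", "given_h", "given_g"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.max_iter < 1 or self.h_tol <= 0 or self.f_tol <= 0:
            raise ValueError("max_iter >= 1 and positive tolerances required")


@dataclass
class VariationalState:
    """Converged variational quantities of one E-step."""

    g: np.ndarray                 # (T, M) model log-evidence
    h: np.ndarray                 # (T, M) model responsibilities
    free_energy_trace: np.ndarray
    converged: bool
    n_iter: int

    @property
    def free_energy(self) -> float:
        return float(self.free_energy_trace[-1])


@dataclass
class EStepResult:
    varstate: VariationalState
    smoothers: list[SmootherResult]
    post: MarkovPosterior
    filters: list[FilterResult] = field(repr=False, default=None)


def model_log_evidence(ssm, smoothed: SmootherResult, y, R) -> np.ndarray:
    """g_t = -1/2 [ (y_t - G x_t|T)' R^-1 (y_t - G x_t|T) + Tr(R^-1 G S_t|T G') ].

    The log|2 pi R| constant is omitted; it is common across candidate models.
    """
    obs = as_observations(y)
    Rinv = np.linalg.inv(R)
    G = ssm.G
    resid = obs.y - smoothed.x_smooth[1:] @ G.T
    quad = np.einsum("ti,ij,tj->t", resid, Rinv, resid)
    GS = np.einsum("pi,tij,qj->tpq", G, smoothed.P_smooth[1:], G)
    tr = np.einsum("pq,tqp->t", Rinv, GS)
    return -0.5 * (quad + tr)


def anneal_evidence(g: np.ndarray, h: np.ndarray, temperature: float):
    """Temperature-scaled statistics: both g and h are divided by T (T=1 is identity)."""
    if temperature < 1:
        raise ValueError("temperature must be >= 1")
    if temperature == 1.0:
        return g, h
    return g / temperature, h / temperature


def init_evidence_interpolated(model: SwitchingModel, y, center: Optional[bool] = None) -> np.ndarray:
    """Initial (T, M) log-evidence from leave-one-out predictive densities.

    With ``center`` (default: on iff candidate state dimensions differ), each
    column is mean-centred over time so that nested candidates with more
    hidden components are not systematically favoured.
    """
    obs = as_observations(y)
    if center is None:
        center = len(set(model.dims)) > 1
    g = np.column_stack(
        [interpolated_log_density(ssm, obs, model.R) for ssm in model.ssms]
    )
    if center:
        g = g - g.mean(axis=0, keepdims=True)
    return g


def _partition_sum(filters) -> float:
    return float(sum(f.partition_steps.sum() for f in filters))


def _free_energy_terms(model, T, logZ, h, g_fb, filters) -> float:
    sign, logdetR = np.linalg.slogdet(model.R)
    const = -0.5 * T * (model.p * _LOG2PI + logdetR)
    return const + logZ + _partition_sum(filters) - float((h * g_fb).sum())


def negative_free_energy(
    model: SwitchingModel, y, varstate: VariationalState, smoothers, post: MarkovPosterior
) -> float:
    """F(q, theta) assembled from the chain normalizer and h-weighted filters.

    q_s is the chain posterior built from post.log_evidence; q_x are the
    per-model smoothers under responsibilities h.  Recovers the exact Kalman
    log-likelihood when M = 1.
    """
    obs = as_observations(y)
    h = post.h
    filters = [
        kalman_filter(ssm, obs, model.R, h[:, m]) for m, ssm in enumerate(model.ssms)
    ]
    return _free_energy_terms(model, obs.T, post.logZ, h, post.log_evidence, filters)


def _smooth_all(model, obs, h):
    filters, smoothers = [], []
    for m, ssm in enumerate(model.ssms):
        filt = kalman_filter(ssm, obs, model.R, h[:, m])
        filters.append(filt)
        smoothers.append(rts_smooth(ssm, filt))
    return filters, smoothers


def fixed_point_estep(
    model: SwitchingModel,
    y,
    cfg: Optional[EStepConfig] = None,
    anneal: Optional[AnnealingSchedule] = None,
    g_init: Optional[np.ndarray] = None,
    h_init: Optional[np.ndarray] = None,
) -> EStepResult:
    """Run the fixed-point iterations to (local) convergence.

    Initialization per cfg.init_mode:
      - "interpolated": start the cycle at forward-backward with interpolated
        log-densities (optionally mean-centred) as g, or with ``g_init``.
      - "annealed": start at the smoothing step with equal responsibilities
        h = 1/M (or ``h_init``), with g and h divided by the scheduled
        temperature; iterations beyond the schedule run at T = 1.
      - "given_g"/"given_h": warm starts from the supplied arrays.

    Stops when max|dh| < h_tol and the relative change of F is below f_tol,
    when F stops increasing (at unit temperature), or at max_iter.
    """
    cfg = cfg or EStepConfig()
    obs = as_observations(y)
    T, M = obs.T, model.M

    mode = cfg.init_mode
    temps = None
    if mode == "annealed":
        anneal = anneal or AnnealingSchedule()
        temps = anneal.temperatures()
        h = np.full((T, M), 1.0 / M) if h_init is None else np.asarray(h_init, float)
        g = None
    elif mode == "interpolated":
        g = init_evidence_interpolated(model, obs, cfg.center_evidence) if g_init is None else np.asarray(g_init, float)
        h = None
    elif mode == "given_g":
        if g_init is None:
            raise ValueError("given_g requires g_init")
        g = np.asarray(g_init, float)
        h = None
    else:  # given_h
        if h_init is None:
            raise ValueError("given_h requires h_init")
        h = np.asarray(h_init, float)
        g = None

    f_trace: list[float] = []
    best = None    # best unit-temperature state (F, state tuple)
    last = None
    post = None
    prev_h = None
    converged = False
    stopped = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        temp = float(temps[it - 1]) if (temps is not None and it - 1 < len(temps)) else 1.0
        if g is not None:
            # steps 1-2: chain posterior and responsibilities from evidence
            g_fb = g / temp if temp != 1.0 else g
            post = forward_backward(g_fb, model.chain)
            h = post.h
        h_eff = h / temp if temp != 1.0 else h
        # steps 3-4: per-model smoothing under R/h, then fresh evidence
        filters, smoothers = _smooth_all(model, obs, h_eff)
        g = np.column_stack(
            [model_log_evidence(ssm, sm, obs, model.R) for ssm, sm in zip(model.ssms, smoothers)]
        )
        if post is None:
            last = (None, (g.copy(), h.copy(), smoothers, None, filters))
            continue
        F = _free_energy_terms(model, T, post.logZ, h_eff, post.log_evidence, filters)
        if not np.isfinite(F):
            raise FloatingPointError(f"non-finite free energy at fixed-point iteration {it}")
        f_trace.append(F)
        state = (g.copy(), h.copy(), smoothers, post, filters)
        last = (F, state)
        if temp == 1.0:
            if best is not None and F < best[0] - 1e-10:
                stopped = True  # F stopped increasing: keep the best state
                break
            if best is None or F >= best[0]:
                best = (F, state)
            dh = np.inf if prev_h is None else float(np.abs(h - prev_h).max())
            if len(f_trace) >= 2 and dh < cfg.h_tol:
                dF = abs(f_trace[-1] - f_trace[-2]) / max(1.0, abs(f_trace[-1]))
                if dF < cfg.f_tol:
                    converged = True
                    break
            prev_h = h.copy()

    chosen = best if (best is not None and (stopped or converged)) else (best or last)
    F_b, (g_b, h_b, smoothers, post, filters) = chosen if chosen[1][3] is not None else last
    if post is None:
        # annealed/given_h runs that never reached the forward-backward step
        post = forward_backward(g_b, model.chain)
        filters, smoothers = _smooth_all(model, obs, post.h)
        h_b = post.h.copy()
        F = _free_energy_terms(model, T, post.logZ, h_b, post.log_evidence, filters)
        f_trace.append(F)
    varstate = VariationalState(
        g=g_b, h=h_b, free_energy_trace=np.asarray(f_trace), converged=converged, n_iter=it
    )
    return EStepResult(varstate, smoothers, post, filters)
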