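"""Generalized EM: sufficient statistics, (tied) M-step updates, and the VB-EM driver.

The E-step is the structured variational approximation from
:mod:`switchssm.variational`; the M-step maximizes the expected complete
log-likelihood in closed form.  Parameter tying pools the relevant
sufficient statistics across the tied group before solving, which is the
stationary point of the summed expected complete log-likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .em import MapPriors, _oscillator_update, apply_blocks
from .hmm import MarkovPosterior
from .model import SwitchingModel, TyingSpec
from .ssm import as_observations
from .variational import (
    AnnealingSchedule,
    EStepConfig,
    EStepResult,
    fixed_point_estep,
)

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class ModelStats:
    """Per-candidate second-moment statistics feeding the M-step."""

    A: np.ndarray      # sum_t E[x_{t-1} x_{t-1}']
    B: np.ndarray      # sum_t E[x_t x_{t-1}']
    C: np.ndarray      # sum_t E[x_t x_t']
    x0: np.ndarray     # E[x_0]
    P0: np.ndarray     # Cov[x_0]
    Syy_h: np.ndarray  # sum_t h_t y_t y_t'
    Syx_h: np.ndarray  # sum_t h_t y_t E[x_t]'
    Sxx_h: np.ndarray  # sum_t h_t E[x_t x_t']
    h_sum: float


@dataclass
class SufficientStats:
    per_model: list[ModelStats]
    p0: np.ndarray        # (M,) marginal of s_0
    pair_sum: np.ndarray  # (M, M) sum_t p_{t,t-1|T}(m, n)
    h: np.ndarray         # (T, M)
    T: int


@dataclass
class EMConfig:
    """Outer-loop controls and per-parameter update flags."""

    max_em_iter: int = 50
    f_rel_tol: float = 1e-6
    update_mu: bool = True
    update_Q0: bool = True
    update_F: bool = True
    update_Q: bool = True
    update_G: bool = False
    update_R: bool = True
    update_rho: bool = True
    update_phi: bool = True
    priors: Optional[MapPriors] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.max_em_iter < 1:
            raise ValueError("max_em_iter must be >= 1")


def collect_stats(smoothers, post: MarkovPosterior, y) -> SufficientStats:
    obs = as_observations(y)
    h = post.h
    per = []
    for m, sm in enumerate(smoothers):
        xs, Ps, Plag = sm.x_smooth, sm.P_smooth, sm.P_lag
        A = Ps[:-1].sum(axis=0) + xs[:-1].T @ xs[:-1]
        C = Ps[1:].sum(axis=0) + xs[1:].T @ xs[1:]
        B = Plag.sum(axis=0) + xs[1:].T @ xs[:-1]
        hm = h[:, m]
        Syy = (obs.y * hm[:, None]).T @ obs.y
        Syx = (obs.y * hm[:, None]).T @ xs[1:]
        Exx = Ps[1:] + np.einsum("ti,tj->tij", xs[1:], xs[1:])
        Sxx = np.einsum("t,tij->ij", hm, Exx)
        per.append(
            ModelStats(A, B, C, xs[0].copy(), Ps[0].copy(), Syy, Syx, Sxx, float(hm.sum()))
        )
    return SufficientStats(per, post.p0.copy(), post.pairwise.sum(axis=0), h.copy(), obs.T)


def expected_complete_loglik(model: SwitchingModel, stats: SufficientStats) -> float:
    """Expected complete log-likelihood of the switching model under q (up to no constants)."""
    T = stats.T
    Rinv = np.linalg.inv(model.R)
    sign, logdetR = np.linalg.slogdet(model.R)
    val = -0.5 * T * (model.p * _LOG2PI + logdetR)
    with np.errstate(divide="ignore"):
        logrho = np.log(model.chain.rho)
        logphi = np.log(model.chain.phi)
    for m, (ssm, st) in enumerate(zip(model.ssms, stats.per_model)):
        G, F = ssm.G, ssm.F
        obs_quad = (
            st.Syy_h - G @ st.Syx_h.T - st.Syx_h @ G.T + G @ st.Sxx_h @ G.T
        )
        val -= 0.5 * float(np.trace(Rinv @ obs_quad))
        s0, ld0 = np.linalg.slogdet(2.0 * np.pi * ssm.Q0)
        d0 = st.x0 - ssm.mu
        val -= 0.5 * (ld0 + float(d0 @ np.linalg.solve(ssm.Q0, d0))
                      + float(np.trace(np.linalg.solve(ssm.Q0, st.P0))))
        sq, ldq = np.linalg.slogdet(2.0 * np.pi * ssm.Q)
        Sdyn = st.C - st.B @ F.T - F @ st.B.T + F @ st.A @ F.T
        val -= 0.5 * (T * ldq + float(np.trace(np.linalg.solve(ssm.Q, Sdyn))))
    val += float(np.where(stats.p0 > 0, stats.p0 * logrho, 0.0).sum())
    val += float(np.where(stats.pair_sum > 0, stats.pair_sum * logphi, 0.0).sum())
    return val


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------


def _untied_f_q(model, stats, cfg):
    for ssm, st in zip(model.ssms, stats.per_model):
        if cfg.update_F:
            try:
                F = np.linalg.solve(st.A.T, st.B.T).T
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    "singular state second-moment matrix A in the F update"
                ) from exc
            ssm.F = F
        if cfg.update_Q:
            F = ssm.F
            Qn = (st.C - st.B @ F.T - F @ st.B.T + F @ st.A @ F.T) / stats.T
            ssm.Q = 0.5 * (Qn + Qn.T)


def _tied_f(model, stats, tying: TyingSpec):
    """Pooled normal equations over the free entries of all F matrices.

    Unknowns are one value per group plus one per singleton free entry; the
    stationarity conditions sum tr(E_k' Qinv (F A - B)) over models, weighted
    by each model's current state-noise precision.
    """
    M = model.M
    d = model.ssms[0].d
    free = tying.f_free
    if free is None:
        free = [np.ones((s.d, s.d), dtype=bool) for s in model.ssms]
    group_of = {}
    groups = [list(map(tuple, grp)) for grp in tying.f_groups]
    for k, grp in enumerate(groups):
        for ent in grp:
            group_of[ent] = k
    params = [grp[:] for grp in groups]
    for m in range(M):
        for i in range(model.ssms[m].d):
            for j in range(model.ssms[m].d):
                ent = (m, i, j)
                if free[m][i, j] and ent not in group_of:
                    group_of[ent] = len(params)
                    params.append([ent])
    K = len(params)
    Qinv = [np.linalg.inv(s.Q) for s in model.ssms]
    # fixed part of F: entries outside the free mask keep their current value
    F0 = [np.where(free[m], 0.0, model.ssms[m].F) for m in range(M)]
    H = np.zeros((K, K))
    rhs = np.zeros(K)
    for k, grp_k in enumerate(params):
        for (m, i, j) in grp_k:
            st = stats.per_model[m]
            rhs[k] += (Qinv[m] @ (st.B - F0[m] @ st.A))[i, j]
            for l, grp_l in enumerate(params):
                for (m2, i2, j2) in grp_l:
                    if m2 != m:
                        continue
                    H[k, l] += Qinv[m][i, i2] * st.A[j2, j]
    theta = np.linalg.solve(H, rhs)
    for m in range(M):
        Fm = F0[m].copy()
        for k, grp in enumerate(params):
            for (m2, i, j) in grp:
                if m2 == m:
                    Fm[i, j] = theta[k]
        model.ssms[m].F = Fm


def _tied_q(model, stats, tying: TyingSpec, cfg):
    grouped = set()
    for grp in tying.q_groups:
        S = np.zeros_like(model.ssms[grp[0]].Q)
        for m in grp:
            st = stats.per_model[m]
            F = model.ssms[m].F
            S += st.C - st.B @ F.T - F @ st.B.T + F @ st.A @ F.T
            grouped.add(m)
        Qn = S / (len(grp) * stats.T)
        Qn = 0.5 * (Qn + Qn.T)
        for m in grp:
            model.ssms[m].Q = Qn.copy()
    for m in range(model.M):
        if m not in grouped and cfg.update_Q:
            st = stats.per_model[m]
            F = model.ssms[m].F
            Qn = (st.C - st.B @ F.T - F @ st.B.T + F @ st.A @ F.T) / stats.T
            model.ssms[m].Q = 0.5 * (Qn + Qn.T)


def _osc_mstep(model, stats, tying: TyingSpec, cfg):
    """Structured (a, omega, sigma2) updates with oscillator-block pooling."""
    done = set()
    groups = [list(map(tuple, grp)) for grp in tying.osc_groups]
    singles = [
        [(m, bi)]
        for m, ssm in enumerate(model.ssms)
        for bi in range(len(ssm.blocks or []))
        if all((m, bi) not in grp for grp in groups)
    ]
    for grp in groups + singles:
        A = B = C = None
        for (m, bi) in grp:
            b = model.ssms[m].blocks[bi]
            sl = slice(b.start, b.start + 2)
            st = stats.per_model[m]
            if A is None:
                A, B, C = st.A[sl, sl].copy(), st.B[sl, sl].copy(), st.C[sl, sl].copy()
            else:
                A += st.A[sl, sl]
                B += st.B[sl, sl]
                C += st.C[sl, sl]
        lead = model.ssms[grp[0][0]].blocks[grp[0][1]]
        a, w, s2 = _oscillator_update(A, B, C, len(grp) * stats.T, lead, cfg.priors)
        for (m, bi) in grp:
            blk = model.ssms[m].blocks[bi]
            blk.a, blk.omega, blk.sigma2 = a, w, s2
        done.add(id(lead))
    for ssm in model.ssms:
        apply_blocks(ssm)


def _update_r(model, stats, cfg):
    T = stats.T
    if model.tying.shared_r:
        S = np.zeros((model.p, model.p))
        for ssm, st in zip(model.ssms, stats.per_model):
            G = ssm.G
            S += st.Syy_h - G @ st.Syx_h.T - st.Syx_h @ G.T + G @ st.Sxx_h @ G.T
        if cfg.priors is not None and model.p == 1:
            Rn = (S + 2.0 * cfg.priors.r_scale) / (T + 2.0 * (cfg.priors.r_shape + 1.0))
        else:
            Rn = S / T
        model.R = 0.5 * (Rn + Rn.T)
    else:
        # per-model R is not stored on SwitchingModel; pooled form is the default
        raise NotImplementedError("per-model R requires per_model_r_update")


def per_model_r_update(model, stats):
    """Per-model observation-noise updates R^(m) (responsibility-normalized)."""
    out = []
    for ssm, st in zip(model.ssms, stats.per_model):
        G = ssm.G
        S = st.Syy_h - G @ st.Syx_h.T - st.Syx_h @ G.T + G @ st.Sxx_h @ G.T
        out.append(0.5 * (S + S.T) / max(st.h_sum, 1e-12))
    return out


def mstep(model: SwitchingModel, stats: SufficientStats, cfg: Optional[EMConfig] = None) -> SwitchingModel:
    """Closed-form parameter updates maximizing the expected complete log-likelihood.

    Tied groups pool statistics across members before solving; with a trivial
    tying spec the classical untied updates are used directly.
    """
    cfg = cfg or EMConfig()
    model = model.copy()
    tying = model.tying
    if cfg.update_mu or cfg.update_Q0:
        for ssm, st in zip(model.ssms, stats.per_model):
            mu_new = st.x0 if cfg.update_mu else ssm.mu
            if cfg.update_Q0:
                dev = st.x0 - mu_new
                Q0n = st.P0 + np.outer(dev, dev)
                ssm.Q0 = 0.5 * (Q0n + Q0n.T)
            ssm.mu = mu_new.copy() if cfg.update_mu else ssm.mu
    oscillatory = all(s.blocks is not None for s in model.ssms)
    if oscillatory and (cfg.update_F or cfg.update_Q):
        _osc_mstep(model, stats, tying, cfg)
    elif tying.is_trivial():
        _untied_f_q(model, stats, cfg)
    else:
        if cfg.update_F:
            _tied_f(model, stats, tying)
        if cfg.update_Q:
            _tied_q(model, stats, tying, cfg)
    if cfg.update_G:
        for ssm, st in zip(model.ssms, stats.per_model):
            ssm.G = np.linalg.solve(st.Sxx_h.T, st.Syx_h.T).T
    if cfg.update_R:
        _update_r(model, stats, cfg)
    if cfg.update_rho:
        model.chain.rho = stats.p0 / stats.p0.sum()
    if cfg.update_phi:
        colsum = stats.pair_sum.sum(axis=0)
        phi = model.chain.phi.copy()
        ok = colsum > 0  # a fully vetoed source state keeps its previous column
        phi[:, ok] = stats.pair_sum[:, ok] / colsum[ok]
        model.chain.phi = phi
    model.chain.__post_init__()
    return model


@dataclass
class VBEMResult:
    model: SwitchingModel
    varstate: "object"
    estep: EStepResult
    free_energy_trace: np.ndarray
    n_iter: int
    converged: bool


def vbem(
    model: SwitchingModel,
    y,
    ecfg: Optional[EStepConfig] = None,
    mcfg: Optional[EMConfig] = None,
    anneal: Optional[AnnealingSchedule] = None,
) -> VBEMResult:
    """Alternate variational E-steps and M-steps until the free energy stabilizes.

    Interpolated-mode E-steps recompute the interpolated-density evidence
    from the current parameters at every E-step; annealed-mode E-steps warm
    start from the previous responsibilities (they are not re-initialized)
    while re-applying the temperature schedule, following the original
    annealing recipe.
    """
    ecfg = ecfg or EStepConfig()
    mcfg = mcfg or EMConfig()
    obs = as_observations(y)
    model = model.copy()
    trace = []
    res = None
    converged = False
    best_F = -np.inf
    stall = 0
    it = 0
    for it in range(1, mcfg.max_em_iter + 1):
        if ecfg.init_mode == "annealed" and res is not None:
            res = fixed_point_estep(model, obs, ecfg, anneal=anneal, h_init=res.varstate.h)
        else:
            res = fixed_point_estep(model, obs, ecfg, anneal=anneal)
        F = res.varstate.free_energy
        if trace and F < trace[-1] - 1e-6 * max(1.0, abs(trace[-1])):
            # re-initialized E-steps make generalized EM only weakly monotone
            logger.warning("free energy decreased at EM iteration %d (%.6g -> %.6g)", it, trace[-1], F)
        trace.append(F)
        # stop once F stops improving on its running best for a few iterations
        if F > best_F + mcfg.f_rel_tol * max(1.0, abs(F)):
            best_F = F
            stall = 0
        else:
            stall += 1
            if stall >= 3:
                converged = True
                break
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < mcfg.f_rel_tol * max(1.0, abs(F)):
            converged = True
            break
        stats = collect_stats(res.smoothers, res.post, obs)
        model = mstep(model, stats, mcfg)
    return VBEMResult(model, res.varstate, res, np.asarray(trace), it, converged)
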