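"""Stationary (non-switching) EM for a single Gaussian SSM.

Used to initialize oscillator parameters before switching inference, and as
the classical Shumway-Stoffer baseline fit.  Supports plain linear updates
and oscillator-structured updates (damped rotation blocks parameterized by
damping a, frequency omega and isotropic noise sigma2), optionally with MAP
priors on omega, sigma2 and R.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ssm import GaussianSSM, as_observations, _as_R, kalman_filter, rts_smooth


@dataclass
class MapPriors:
    """Weakly-informative MAP priors for oscillator-structured updates.

    omega_std_hz
        Standard deviation of a Gaussian prior on each block's rotation
        frequency (in Hz), centred at the frequency the block had when the
        priors object was bound to a model (see ``bind``).
    sigma2_shape / sigma2_scale, r_shape / r_scale
        Inverse-gamma (shape, scale) priors on the state-noise variance of
        each block and on a scalar observation noise R.
    """

    omega_std_hz: float = 1.0
    sigma2_shape: float = 0.1
    sigma2_scale: float = 0.1
    r_shape: float = 0.1
    r_scale: float = 0.1
    omega_centers: Optional[dict] = None  # (block name) -> radians/sample
    fs: float = 1.0

    def bind(self, ssm: GaussianSSM, fs: float) -> "MapPriors":
        """Centre the omega priors at the model's current block frequencies."""
        import copy

        out = copy.deepcopy(self)
        out.fs = fs
        out.omega_centers = {b.name: b.omega for b in (ssm.blocks or [])}
        return out


def _single_stats(sm, y):
    """Sufficient statistics for one model with unit responsibilities."""
    xs, Ps, Plag = sm.x_smooth, sm.P_smooth, sm.P_lag
    T = y.shape[0]
    A = Ps[:-1].sum(axis=0) + xs[:-1].T @ xs[:-1]
    C = Ps[1:].sum(axis=0) + xs[1:].T @ xs[1:]
    B = Plag.sum(axis=0) + xs[1:].T @ xs[:-1]
    Syy = y.T @ y
    Syx = y.T @ xs[1:]
    Sxx = C
    return A, B, C, Syy, Syx, Sxx


def _oscillator_update(A, B, C, T_eff, block, prior: Optional[MapPriors]):
    """Closed-form (a, omega, sigma2) update for one 2-D rotation block.

    Maximizes the expected complete log-likelihood restricted to
    F = a*Rot(omega), Q = sigma2*I2; with a MAP prior on omega the stationary
    point is found by a few Newton steps around the ML angle.
    """
    b1 = B[0, 0] + B[1, 1]
    b2 = B[1, 0] - B[0, 1]
    trA = A[0, 0] + A[1, 1]
    trC = C[0, 0] + C[1, 1]
    r = np.hypot(b1, b2)
    omega_ml = np.arctan2(b2, b1)
    if prior is None or prior.omega_centers is None or block.name not in prior.omega_centers:
        omega = omega_ml
        a = max(r / trA, 1e-12)
    else:
        omega0 = prior.omega_centers[block.name]
        tau = 2.0 * np.pi * prior.omega_std_hz / prior.fs
        a = max(r / trA, 1e-12)
        omega = omega_ml
        # alternate a | omega and Newton on omega | a
        for _ in range(10):
            for _ in range(5):
                grad = (a / _sig2(trC, trA, a, b1, b2, omega, T_eff)) * (
                    -b1 * np.sin(omega) + b2 * np.cos(omega)
                ) - (omega - omega0) / tau**2
                hess = (a / _sig2(trC, trA, a, b1, b2, omega, T_eff)) * (
                    -b1 * np.cos(omega) - b2 * np.sin(omega)
                ) - 1.0 / tau**2
                if hess >= 0:
                    break
                omega -= grad / hess
            a_new = max((b1 * np.cos(omega) + b2 * np.sin(omega)) / trA, 1e-12)
            if abs(a_new - a) < 1e-12:
                a = a_new
                break
            a = a_new
    resid = trC - 2.0 * a * (b1 * np.cos(omega) + b2 * np.sin(omega)) + a * a * trA
    if prior is None:
        sigma2 = resid / (2.0 * T_eff)
    else:
        sigma2 = (resid + 2.0 * prior.sigma2_scale) / (2.0 * T_eff + 2.0 * (prior.sigma2_shape + 1.0))
    sigma2 = max(sigma2, 1e-12)
    return float(a), float(omega), float(sigma2)


def rotation(a: float, omega: float) -> np.ndarray:
    c, s = np.cos(omega), np.sin(omega)
    return a * np.array([[c, -s], [s, c]])


def apply_blocks(ssm: GaussianSSM) -> None:
    """Rewrite F and Q from the model's oscillator-block parameters in place."""
    for b in ssm.blocks:
        sl = slice(b.start, b.start + 2)
        ssm.F[sl, sl] = rotation(b.a, b.omega)
        ssm.Q[sl, sl] = b.sigma2 * np.eye(2)


def stationary_em(
    ssm: GaussianSSM,
    y,
    R,
    n_iter: int = 50,
    update_initial: bool = False,
    priors: Optional[MapPriors] = None,
):
    """EM for a single Gaussian SSM; returns (fitted ssm, R, log-likelihood trace).

    If the model carries oscillator blocks, the structured (a, omega, sigma2)
    updates are used; otherwise the unconstrained linear-Gaussian M-step
    (F = B A^{-1}, etc.).  With ``update_initial`` False, mu and Q0 are held
    fixed.  ``priors`` enables MAP updates (oscillator-structured models only).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    obs = as_observations(y)
    T = obs.T
    ssm = ssm.copy()
    R = _as_R(R, ssm.p)
    trace = []
    for it in range(n_iter):
        filt = kalman_filter(ssm, obs, R)
        ll = filt.loglik
        if not np.isfinite(ll):
            raise FloatingPointError(f"non-finite log-likelihood at EM iteration {it}")
        trace.append(ll)
        sm = rts_smooth(ssm, filt)
        A, B, C, Syy, Syx, Sxx = _single_stats(sm, obs.y)
        if ssm.blocks is not None:
            for b in ssm.blocks:
                sl = slice(b.start, b.start + 2)
                b.a, b.omega, b.sigma2 = _oscillator_update(
                    A[sl, sl], B[sl, sl], C[sl, sl], T, b, priors
                )
            apply_blocks(ssm)
        else:
            F = np.linalg.solve(A.T, B.T).T
            Qn = (C - B @ F.T - F @ B.T + F @ A @ F.T) / T
            ssm.F = F
            ssm.Q = 0.5 * (Qn + Qn.T)
        # observation noise (G fixed): R = (1/T) sum_t E[(y - Gx)(y - Gx)']
        G = ssm.G
        Rn = (Syy - G @ Syx.T - Syx @ G.T + G @ Sxx @ G.T) / T
        if priors is not None and ssm.p == 1:
            Rn = (Rn * T + 2.0 * priors.r_scale) / (T + 2.0 * (priors.r_shape + 1.0))
        R = 0.5 * (Rn + Rn.T)
        wR = np.linalg.eigvalsh(R).min()
        if wR < 1e-12:
            R = R + (1e-12 - min(wR, 0.0)) * np.eye(ssm.p)
        if update_initial:
            ssm.mu = sm.x_smooth[0].copy()
            ssm.Q0 = 0.5 * (sm.P_smooth[0] + sm.P_smooth[0].T)
        w = np.linalg.eigvalsh(ssm.Q)
        if w.min() < -1e-10:
            raise FloatingPointError(f"non-PSD Q update at EM iteration {it}")
    filt = kalman_filter(ssm, obs, R)
    trace.append(filt.loglik)
    return ssm, R, np.asarray(trace)


def _sig2(trC, trA, a, b1, b2, omega, T_eff):
    resid = trC - 2.0 * a * (b1 * np.cos(omega) + b2 * np.sin(omega)) + a * a * trA
    return max(resid / (2.0 * T_eff), 1e-12)
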