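"""Linear-Gaussian state-space models and exact inference primitives.

The state is indexed t = 0..T with x_0 ~ N(mu, Q0) and no emission at t = 0;
observations y_t run t = 1..T (stored at array index t-1).  All covariance
outputs are symmetrized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._core import (
    backward_info_core,
    interp_core,
    kalman_core,
    rts_core,
)

#: responsibilities below this threshold skip the measurement update entirely
SKIP_EPS = 1e-12


class InvalidModelError(ValueError):
    """Raised when a model violates shape or positive-semidefiniteness constraints."""


def _as_cov(A, name: str, dim: int) -> np.ndarray:
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    if A.shape != (dim, dim):
        raise InvalidModelError(f"{name} must be {dim}x{dim}, got {A.shape}")
    if not np.allclose(A, A.T, atol=1e-10):
        raise InvalidModelError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(0.5 * (A + A.T))
    if w.min() < -1e-10 * max(1.0, abs(w.max())):
        raise InvalidModelError(f"{name} must be positive semi-definite")
    return 0.5 * (A + A.T)


@dataclass
class OscillatorBlock:
    """A 2-D damped-rotation block a*Rot(omega) with isotropic noise sigma2*I2."""

    name: str
    a: float
    omega: float  # radians per sample
    sigma2: float
    start: int  # index of the block's first state coordinate


@dataclass
class GaussianSSM:
    """One linear-Gaussian candidate model.

    Parameters
    ----------
    mu, Q0
        Initial state mean (d,) and covariance (d, d).
    F, Q
        State-transition matrix and state-noise covariance (d, d).
    G
        Observation matrix (p, d).
    blocks
        Optional oscillator-block structure of F/Q (set by the model builders);
        enables structured (a, omega, sigma2) M-step updates.
    """

    mu: np.ndarray
    Q0: np.ndarray
    F: np.ndarray
    Q: np.ndarray
    G: np.ndarray
    blocks: Optional[list[OscillatorBlock]] = None

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=np.float64))
        d = self.mu.shape[0]
        self.F = np.atleast_2d(np.asarray(self.F, dtype=np.float64))
        if self.F.shape != (d, d):
            raise InvalidModelError(f"F must be {d}x{d}, got {self.F.shape}")
        self.Q0 = _as_cov(self.Q0, "Q0", d)
        self.Q = _as_cov(self.Q, "Q", d)
        self.G = np.atleast_2d(np.asarray(self.G, dtype=np.float64))
        if self.G.shape[1] != d:
            raise InvalidModelError(f"G must have {d} columns, got {self.G.shape}")

    @property
    def d(self) -> int:
        return self.mu.shape[0]

    @property
    def p(self) -> int:
        return self.G.shape[0]

    def copy(self) -> "GaussianSSM":
        import copy as _copy

        return GaussianSSM(
            self.mu.copy(), self.Q0.copy(), self.F.copy(), self.Q.copy(), self.G.copy(),
            blocks=_copy.deepcopy(self.blocks),
        )


@dataclass
class Observations:
    """Observed series y (T, p) with an optional sampling rate in Hz."""

    y: np.ndarray
    fs: Optional[float] = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=np.float64)
        if y.ndim == 1:
            y = y[:, None]
        if y.ndim != 2 or y.shape[0] < 1:
            raise ValueError("y must be a (T, p) array with T >= 1")
        if not np.isfinite(y).all():
            raise ValueError("y contains non-finite values (missing data unsupported)")
        self.y = np.ascontiguousarray(y)

    @property
    def T(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.y.shape[1]


def as_observations(y) -> Observations:
    return y if isinstance(y, Observations) else Observations(y)


def _as_R(R, p: int) -> np.ndarray:
    R = np.asarray(R, dtype=np.float64)
    if R.ndim == 0:
        R = R * np.eye(p)
    R = _as_cov(R, "R", p)
    if np.linalg.eigvalsh(R).min() <= 0:
        raise InvalidModelError("R must be positive definite")
    return R


@dataclass
class FilterResult:
    """Kalman-filter output; array index i corresponds to time t = i+1."""

    x_pred: np.ndarray
    P_pred: np.ndarray
    x_filt: np.ndarray
    P_filt: np.ndarray
    loglik_steps: np.ndarray
    partition_steps: np.ndarray = field(repr=False, default=None)
    h: np.ndarray = field(repr=False, default=None)

    @property
    def loglik(self) -> float:
        return float(self.loglik_steps.sum())


@dataclass
class SmootherResult:
    """RTS output; x_smooth/P_smooth index t = 0..T, P_lag[i] = Cov(x_{i+1}, x_i | y)."""

    x_smooth: np.ndarray
    P_smooth: np.ndarray
    P_lag: np.ndarray


def kalman_filter(ssm: GaussianSSM, y, R, h: Optional[np.ndarray] = None) -> FilterResult:
    """Kalman filter with effective observation noise R / h_t.

    With ``h`` absent the standard filter is run (identical to ``h`` of ones).
    Steps with h_t <= SKIP_EPS skip the measurement update and contribute zero
    log-likelihood increments.
    """
    obs = as_observations(y)
    R = _as_R(R, ssm.p)
    if ssm.p != obs.p:
        raise ValueError(f"observation dimension mismatch: model p={ssm.p}, data p={obs.p}")
    if h is None:
        h = np.ones(obs.T)
    else:
        h = np.asarray(h, dtype=np.float64)
        if h.shape != (obs.T,):
            raise ValueError("h must have length T")
        if h.min() < -1e-12 or h.max() > 1 + 1e-9:
            raise ValueError("h entries must lie in [0, 1]")
        h = np.clip(h, 0.0, None)
    xp, Pp, xf, Pf, ll, part = kalman_core(
        ssm.F, ssm.Q, ssm.G, R, ssm.mu, ssm.Q0, obs.y, h, SKIP_EPS
    )
    return FilterResult(xp, Pp, xf, Pf, ll, part, h)


def rts_smooth(ssm: GaussianSSM, filt: FilterResult) -> SmootherResult:
    """Rauch-Tung-Striebel smoother with lag-one smoothed cross-covariances."""
    xs, Ps, Plag = rts_core(
        ssm.F, filt.x_pred, filt.P_pred, filt.x_filt, filt.P_filt, ssm.mu, ssm.Q0
    )
    return SmootherResult(xs, Ps, Plag)


def smooth(ssm: GaussianSSM, y, R, h: Optional[np.ndarray] = None):
    """Convenience: filter then smooth; returns (FilterResult, SmootherResult)."""
    filt = kalman_filter(ssm, y, R, h)
    return filt, rts_smooth(ssm, filt)


def interpolated_log_density(ssm: GaussianSSM, y, R) -> np.ndarray:
    """Leave-one-out Gaussian predictive log-densities log p(y_t | y_{1:t-1}, y_{t+1:T}).

    Two-filter construction: the forward Kalman one-step predictive
    N(x_t | y_{1:t-1}) is fused with a backward information-form likelihood
    message from y_{t+1:T}, then pushed through the observation equation.
    Exactly equals conditioning in the dense joint Gaussian.
    """
    obs = as_observations(y)
    R = _as_R(R, ssm.p)
    filt = kalman_filter(ssm, obs, R)
    Rinv = np.linalg.inv(R)
    GtRinv = ssm.G.T @ Rinv
    GtRinvG = GtRinv @ ssm.G
    GtRinv_y = obs.y @ GtRinv.T  # (T, d)
    Lam, lam = backward_info_core(ssm.F, ssm.Q, GtRinvG, np.ascontiguousarray(GtRinv_y))
    sign, logdetR = np.linalg.slogdet(R)
    return interp_core(
        filt.x_pred, filt.P_pred, Lam, lam, ssm.G, Rinv, GtRinvG, GtRinv, logdetR, obs.y
    )


# ---------------------------------------------------------------------------
# dense joint-Gaussian oracle (test plumbing)
# ---------------------------------------------------------------------------

_ORACLE_MAX = 400  # max total dimension of the dense joint


def joint_gaussian_oracle(ssm: GaussianSSM, R, T: int):
    """Exact joint mean/covariance of the stacked vector (x_0..x_T, y_1..y_T).

    Only intended for small instances; refuses when the dense dimension
    exceeds an internal guard.
    """
    R = _as_R(R, ssm.p)
    d, p = ssm.d, ssm.p
    n = (T + 1) * d + T * p
    if n > _ORACLE_MAX:
        raise ValueError(f"joint dimension {n} exceeds the oracle guard ({_ORACLE_MAX})")
    mean = np.zeros(n)
    cov = np.zeros((n, n))

    def xi(t):
        return slice(t * d, (t + 1) * d)

    def yi(t):  # t = 1..T
        off = (T + 1) * d
        return slice(off + (t - 1) * p, off + t * p)

    mean[xi(0)] = ssm.mu
    cov[xi(0), xi(0)] = ssm.Q0
    for t in range(1, T + 1):
        mean[xi(t)] = ssm.F @ mean[xi(t - 1)]
        for j in range(t):
            cov[xi(t), xi(j)] = ssm.F @ cov[xi(t - 1), xi(j)]
            cov[xi(j), xi(t)] = cov[xi(t), xi(j)].T
        cov[xi(t), xi(t)] = ssm.F @ cov[xi(t - 1), xi(t - 1)] @ ssm.F.T + ssm.Q
    for t in range(1, T + 1):
        mean[yi(t)] = ssm.G @ mean[xi(t)]
        for j in range(T + 1):
            cov[yi(t), xi(j)] = ssm.G @ cov[xi(t), xi(j)]
            cov[xi(j), yi(t)] = cov[yi(t), xi(j)].T
        for u in range(1, T + 1):
            cov[yi(t), yi(u)] = ssm.G @ cov[xi(t), xi(u)] @ ssm.G.T
            if u == t:
                cov[yi(t), yi(u)] += R
    cov = 0.5 * (cov + cov.T)
    return mean, cov, xi, yi


def gaussian_condition(mean, cov, obs_idx: Sequence[int], obs_val):
    """Condition a joint Gaussian on components obs_idx taking values obs_val."""
    mean = np.asarray(mean, float)
    cov = np.asarray(cov, float)
    obs_idx = np.asarray(obs_idx, int)
    keep = np.setdiff1d(np.arange(mean.size), obs_idx)
    Saa = cov[np.ix_(keep, keep)]
    Sab = cov[np.ix_(keep, obs_idx)]
    Sbb = cov[np.ix_(obs_idx, obs_idx)]
    resid = np.asarray(obs_val, float) - mean[obs_idx]
    W = np.linalg.solve(Sbb, Sab.T)
    cmean = mean[keep] + Sab @ np.linalg.solve(Sbb, resid)
    ccov = Saa - Sab @ W
    return cmean, 0.5 * (ccov + ccov.T), keep
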