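"""Numba-compiled inner loops for filtering, smoothing, interpolation and HMM message passing.

All kernels operate on contiguous float64 arrays and follow the package's time
convention: the state is indexed t = 0..T with x_0 ~ N(mu, Q0) carrying no
observation, and observations y are indexed t = 1..T (array index t-1).
"""

import numpy as np
from numba import njit

_LOG2PI = float(np.log(2.0 * np.pi))


@njit(cache=True)
def _logdet_chol(A):
    L = np.linalg.cholesky(A)
    s = 0.0
    for i in range(L.shape[0]):
        s += np.log(L[i, i])
    return 2.0 * s


@njit(cache=True)
def kalman_core(F, Q, G, R, mu, Q0, y, h, eps):
    """Kalman filter with per-time responsibility-scaled observation noise R/h_t.

    Returns predicted/filtered moments, per-step predictive log-density
    increments (effective noise; 0 at skipped steps) and per-step
    log-partition increments used by the free energy.
    """
    T, p = y.shape
    d = F.shape[0]
    xp = np.empty((T, d))
    Pp = np.empty((T, d, d))
    xf = np.empty((T, d))
    Pf = np.empty((T, d, d))
    ll = np.zeros(T)
    part = np.zeros(T)
    logdetR = _logdet_chol(R)
    x = mu.copy()
    P = Q0.copy()
    for t in range(T):
        x = F @ x
        P = F @ P @ F.T + Q
        P = 0.5 * (P + P.T)
        xp[t] = x
        Pp[t] = P
        ht = h[t]
        if ht <= eps:
            # vanishing responsibility: measurement update skipped
            xf[t] = x
            Pf[t] = P
            continue
        GP = G @ P
        S = ht * (GP @ G.T) + R
        S = 0.5 * (S + S.T)
        innov = y[t] - G @ x
        logdetS = _logdet_chol(S)
        sol = np.linalg.solve(S, innov)
        quad = innov @ sol
        K = ht * np.linalg.solve(S, GP).T
        x = x + K @ innov
        P = P - K @ GP
        P = 0.5 * (P + P.T)
        xf[t] = x
        Pf[t] = P
        ll[t] = -0.5 * (p * _LOG2PI + logdetS - p * np.log(ht) + ht * quad)
        part[t] = -0.5 * (logdetS - logdetR + ht * quad)
    return xp, Pp, xf, Pf, ll, part


@njit(cache=True)
def rts_core(F, xp, Pp, xf, Pf, mu, Q0):
    """RTS smoother; returns moments for t = 0..T and lag-one cross-covariances.

    Plag[i] = Cov(x_{i+1}, x_i | y_{1:T}), i = 0..T-1.
    """
    T, d = xf.shape
    xs = np.empty((T + 1, d))
    Ps = np.empty((T + 1, d, d))
    Plag = np.empty((T, d, d))
    xs[T] = xf[T - 1]
    Ps[T] = Pf[T - 1]
    for t in range(T - 1, -1, -1):
        if t == 0:
            xft = mu
            Pft = Q0
        else:
            xft = xf[t - 1]
            Pft = Pf[t - 1]
        # J = Pf[t] F' Pp[t+1]^{-1}; Pp index t holds the predictive for time t+1
        J = np.linalg.solve(Pp[t], F @ Pft).T
        xs[t] = xft + J @ (xs[t + 1] - xp[t])
        Ps[t] = Pft + J @ (Ps[t + 1] - Pp[t]) @ J.T
        Ps[t] = 0.5 * (Ps[t] + Ps[t].T)
        Plag[t] = Ps[t + 1] @ J.T
    return xs, Ps, Plag


@njit(cache=True)
def backward_info_core(F, Q, GtRinvG, GtRinv_y):
    """Backward information-form likelihood messages p(y_{t+1:T} | x_t).

    Message t is exp(-x' Lam[t] x / 2 + lam[t]' x) up to a constant that
    cancels in the interpolated-density ratio.
    """
    T = GtRinv_y.shape[0]
    d = F.shape[0]
    Lam = np.zeros((T + 1, d, d))
    lam = np.zeros((T + 1, d))
    I = np.eye(d)
    for t in range(T - 1, -1, -1):
        hatL = Lam[t + 1] + GtRinvG
        hatl = lam[t + 1] + GtRinv_y[t]
        M = hatL @ np.linalg.inv(I + Q @ hatL)
        Lt = F.T @ M @ F
        Lam[t] = 0.5 * (Lt + Lt.T)
        lam[t] = F.T @ np.linalg.solve(I + hatL @ Q, hatl)
    return Lam, lam


@njit(cache=True)
def _log_gauss_integral(m, P, Lam, lam):
    """log of integral N(x; m, P) exp(-x'Lam x/2 + lam'x) dx."""
    d = m.shape[0]
    I = np.eye(d)
    B = I + P @ Lam
    detB = np.linalg.det(B)
    c = lam - Lam @ m
    w = P @ np.linalg.solve(I + Lam @ P, c)
    return -0.5 * np.log(detB) - 0.5 * (m @ Lam @ m) + lam @ m + 0.5 * (c @ w)


@njit(cache=True)
def interp_core(xp, Pp, Lam, lam, G, Rinv, GtRinvG, GtRinv, logdetR, y):
    """Leave-one-out predictive log densities log p(y_t | y_{\\t})."""
    T, p = y.shape
    out = np.empty(T)
    for i in range(T):
        m = xp[i]
        P = Pp[i]
        Lt = Lam[i + 1]
        lt = lam[i + 1]
        yt = y[i]
        const = -0.5 * (p * _LOG2PI + logdetR + yt @ Rinv @ yt)
        LtN = Lt + GtRinvG
        ltN = lt + GtRinv @ yt
        out[i] = const + _log_gauss_integral(m, P, LtN, ltN) - _log_gauss_integral(m, P, Lt, lt)
    return out


@njit(cache=True)
def _lse(v):
    mx = v[0]
    for i in range(1, v.shape[0]):
        if v[i] > mx:
            mx = v[i]
    if mx == -np.inf:
        return -np.inf
    s = 0.0
    for i in range(v.shape[0]):
        s += np.exp(v[i] - mx)
    return mx + np.log(s)


@njit(cache=True)
def fb_core(logg, logrho, logphi):
    """Log-domain forward-backward with an emission-free initial state s_0.

    logg[t-1, m] is the log-evidence of model m at time t (t = 1..T).
    Returns log-alpha (t = 0..T), log-beta (t = 0..T) and logZ.
    """
    T, M = logg.shape
    loga = np.empty((T + 1, M))
    logb = np.empty((T + 1, M))
    loga[0] = logrho
    tmp = np.empty(M)
    for t in range(1, T + 1):
        for m in range(M):
            for n in range(M):
                tmp[n] = logphi[m, n] + loga[t - 1, n]
            loga[t, m] = logg[t - 1, m] + _lse(tmp)
    for m in range(M):
        logb[T, m] = 0.0
    for t in range(T - 1, -1, -1):
        for n in range(M):
            for m in range(M):
                tmp[m] = logphi[m, n] + logg[t, m] + logb[t + 1, m]
            logb[t, n] = _lse(tmp)
    logZ = _lse(loga[T].copy())
    return loga, logb, logZ


@njit(cache=True)
def viterbi_core(logg, logrho, logphi):
    """MAP joint path over s_0..s_T; returns s_1..s_T (0-based labels)."""
    T, M = logg.shape
    delta = np.empty((T + 1, M))
    back = np.zeros((T + 1, M), dtype=np.int64)
    delta[0] = logrho
    for t in range(1, T + 1):
        for m in range(M):
            best = -np.inf
            arg = 0
            for n in range(M):
                v = logphi[m, n] + delta[t - 1, n]
                if v > best:
                    best = v
                    arg = n
            delta[t, m] = logg[t - 1, m] + best
            back[t, m] = arg
    path = np.empty(T, dtype=np.int64)
    best = -np.inf
    arg = 0
    for m in range(M):
        if delta[T, m] > best:
            best = delta[T, m]
            arg = m
    s = arg
    for t in range(T, 0, -1):
        path[t - 1] = s
        s = back[t, s]
    return path
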