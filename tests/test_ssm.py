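"""Exact-inference primitives versus the dense joint-Gaussian oracle."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import switchssm as sw
from switchssm.ssm import gaussian_condition, joint_gaussian_oracle

from conftest import random_R, random_ssm


def _oracle_parts(ssm, R, T):
    mean, cov, xi, yi = joint_gaussian_oracle(ssm, R, T)
    ny = (T + 1) * ssm.d
    yidx = np.arange(ny, ny + T * ssm.p)
    return mean, cov, yidx


@pytest.mark.parametrize("d,p,T,seed", [(1, 1, 3, 0), (1, 1, 6, 1), (2, 1, 5, 2), (3, 2, 5, 3), (4, 2, 4, 4)])
def test_filter_smoother_interpolation_match_joint_gaussian(d, p, T, seed):
    """Filtering, smoothing (incl. lag-one) and leave-one-out densities all
    agree with explicit conditioning in the dense joint Gaussian."""
    rng = np.random.default_rng(seed)
    ssm = random_ssm(rng, d, p)
    R = random_R(rng, p)
    y = rng.standard_normal((T, p))
    mean, cov, yidx = _oracle_parts(ssm, R, T)

    filt = sw.kalman_filter(ssm, y, R)
    ll_oracle = multivariate_normal(mean[yidx], cov[np.ix_(yidx, yidx)]).logpdf(y.ravel())
    assert filt.loglik == pytest.approx(ll_oracle, abs=1e-8)
    assert filt.loglik == pytest.approx(filt.loglik_steps.sum(), abs=1e-12)

    sm = sw.rts_smooth(ssm, filt)
    cmean, ccov, keep = gaussian_condition(mean, cov, yidx, y.ravel())
    xs_o = cmean.reshape(T + 1, d)
    np.testing.assert_allclose(sm.x_smooth, xs_o, atol=1e-8)
    for t in range(T + 1):
        np.testing.assert_allclose(
            sm.P_smooth[t], ccov[t * d:(t + 1) * d, t * d:(t + 1) * d], atol=1e-8
        )
    for t in range(1, T + 1):
        np.testing.assert_allclose(
            sm.P_lag[t - 1], ccov[t * d:(t + 1) * d, (t - 1) * d:t * d], atol=1e-8
        )

    il = sw.interpolated_log_density(ssm, y, R)
    for t in range(1, T + 1):
        rest = [u for u in range(T) if u != t - 1]
        ridx = yidx.reshape(T, p)[rest].ravel()
        tidx = yidx.reshape(T, p)[t - 1]
        cm, cc, kp = gaussian_condition(mean, cov, ridx, y[rest].ravel())
        pos = np.searchsorted(kp, tidx)
        expected = multivariate_normal(cm[pos], cc[np.ix_(pos, pos)]).logpdf(y[t - 1])
        assert il[t - 1] == pytest.approx(expected, abs=1e-8)


def test_filter_tracks_data_when_observation_noise_vanishes():
    ssm = sw.GaussianSSM([0.0], [[1.0]], [[0.0]], [[1.0]], [[1.0]])
    y = np.array([[0.3], [-1.2], [2.0]])
    filt = sw.kalman_filter(ssm, y, 1e-12)
    np.testing.assert_allclose(filt.x_filt[:, 0], y[:, 0], atol=1e-6)


def test_zero_responsibility_skips_measurement_update(rng):
    ssm = random_ssm(rng, 2, 1)
    R = random_R(rng, 1)
    y = rng.standard_normal((5, 1))
    h = np.ones(5)
    h[2] = 0.0
    filt = sw.kalman_filter(ssm, y, R, h)
    np.testing.assert_array_equal(filt.x_filt[2], filt.x_pred[2])
    np.testing.assert_array_equal(filt.P_filt[2], filt.P_pred[2])
    assert filt.loglik_steps[2] == 0.0


def test_unit_responsibilities_bitwise_equal_to_absent(rng):
    ssm = random_ssm(rng, 2, 2)
    R = random_R(rng, 2)
    y = rng.standard_normal((8, 2))
    a = sw.kalman_filter(ssm, y, R)
    b = sw.kalman_filter(ssm, y, R, np.ones(8))
    np.testing.assert_array_equal(a.x_filt, b.x_filt)
    np.testing.assert_array_equal(a.P_filt, b.P_filt)
    np.testing.assert_array_equal(a.loglik_steps, b.loglik_steps)


def test_smoother_boundary_and_symmetry(rng):
    ssm = random_ssm(rng, 3, 1)
    R = random_R(rng, 1)
    y = rng.standard_normal((12, 1))
    filt = sw.kalman_filter(ssm, y, R)
    sm = sw.rts_smooth(ssm, filt)
    np.testing.assert_array_equal(sm.x_smooth[-1], filt.x_filt[-1])
    np.testing.assert_array_equal(sm.P_smooth[-1], filt.P_filt[-1])
    for P in (filt.P_filt, filt.P_pred, sm.P_smooth):
        assert np.abs(P - np.swapaxes(P, -1, -2)).max() < 1e-10
        for Pt in P:
            assert np.linalg.eigvalsh(Pt).min() > -1e-10


def test_scaled_noise_matches_manual_variance_rescale(rng):
    """R/h_t scaling equals running the standard filter with inflated noise."""
    ssm = random_ssm(rng, 1, 1)
    y = rng.standard_normal((4, 1))
    h = np.array([1.0, 0.5, 0.25, 1.0])
    filt = sw.kalman_filter(ssm, y, 0.3, h)
    # manual: iterate with per-step R_t = 0.3 / h_t
    x, P = ssm.mu.copy(), ssm.Q0.copy()
    for t in range(4):
        x = ssm.F @ x
        P = ssm.F @ P @ ssm.F.T + ssm.Q
        S = (ssm.G @ P @ ssm.G.T + 0.3 / h[t])
        K = P @ ssm.G.T / S
        x = x + K @ (y[t] - ssm.G @ x)
        P = P - K @ ssm.G @ P
        np.testing.assert_allclose(filt.x_filt[t], x, atol=1e-10)
        np.testing.assert_allclose(filt.P_filt[t], P, atol=1e-10)


def test_interpolated_density_edge_cases(rng):
    # T = 1: the entry is the unconditional predictive density of y_1
    ssm = random_ssm(rng, 2, 1)
    R = random_R(rng, 1)
    y = rng.standard_normal((1, 1))
    var = (ssm.G @ (ssm.F @ ssm.Q0 @ ssm.F.T + ssm.Q) @ ssm.G.T + R).item()
    mu = (ssm.G @ ssm.F @ ssm.mu).item()
    expected = -0.5 * (np.log(2 * np.pi * var) + (y.item() - mu) ** 2 / var)
    assert sw.interpolated_log_density(ssm, y, R)[0] == pytest.approx(expected, abs=1e-10)
    # iid states (F = 0, mu = 0, Q0 = Q): every entry is the marginal density
    iid = sw.GaussianSSM([0.0], [[2.0]], [[0.0]], [[2.0]], [[1.5]])
    y = rng.standard_normal((6, 1))
    got = sw.interpolated_log_density(iid, y, 0.4)
    var = 1.5 ** 2 * 2.0 + 0.4
    expected = -0.5 * (np.log(2 * np.pi * var) + y[:, 0] ** 2 / var)
    np.testing.assert_allclose(got, expected, atol=1e-10)


def test_oracle_marginal_variance_and_independence():
    ssm = sw.GaussianSSM([0.0], [[0.7]], [[0.5]], [[1.2]], [[1.0]])
    R = np.array([[0.3]])
    mean, cov, xi, yi = joint_gaussian_oracle(ssm, R, 2)
    v1 = (ssm.G @ (ssm.F @ ssm.Q0 @ ssm.F.T + ssm.Q) @ ssm.G.T + R).item()
    assert cov[yi(1), yi(1)].item() == pytest.approx(v1, abs=1e-12)
    # F = 0 makes distinct-time observations independent
    white = sw.GaussianSSM([0.0], [[0.7]], [[0.0]], [[1.2]], [[1.0]])
    _, cov0, _, yi0 = joint_gaussian_oracle(white, R, 3)
    assert cov0[yi0(1), yi0(3)].item() == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        joint_gaussian_oracle(ssm, R, 10_000)


def test_invalid_models_and_shapes_rejected(rng):
    with pytest.raises(sw.ssm.InvalidModelError):
        sw.GaussianSSM([0.0], [[-1.0]], [[0.5]], [[1.0]], [[1.0]])
    with pytest.raises(sw.ssm.InvalidModelError):
        sw.GaussianSSM([0.0, 0.0], np.eye(2), np.eye(3), np.eye(2), [[1.0, 0.0]])
    ssm = random_ssm(rng, 1, 1)
    with pytest.raises(ValueError):
        sw.kalman_filter(ssm, rng.standard_normal((4, 2)), np.eye(2))
    with pytest.raises(ValueError):
        sw.kalman_filter(ssm, rng.standard_normal((4, 1)), 0.1, h=np.ones(3))


def test_stationary_em_loglik_nondecreasing(rng):
    ssm_true = random_ssm(rng, 1, 1, stable=0.8)
    R = np.array([[0.4]])
    sim = sw.simulate(
        sw.SwitchingModel([ssm_true], sw.MarkovChainParams([1.0], [[1.0]]), R), 150, 3
    )
    start = random_ssm(rng, 1, 1, stable=0.5)
    fitted, Rf, trace = sw.stationary_em(start, sim.y, 1.0, n_iter=25)
    assert np.all(np.diff(trace) > -1e-8)
    # starting at the truth, one iteration must not decrease the likelihood
    _, _, tr2 = sw.stationary_em(ssm_true, sim.y, R, n_iter=1)
    assert tr2[1] >= tr2[0] - 1e-8


def test_oscillator_em_runs_fifty_iterations_to_finite_parameters():
    """Two-oscillator stationary EM at the spindle initialization settings."""
    from switchssm.models import OscillatorSpec, _stack_oscillators
    from switchssm.spindle import synthesize_sleep_eeg

    y, _ = synthesize_sleep_eeg(duration_s=10.0, seed=11)
    slow = OscillatorSpec(0.98, 1.0, 100.0, 1.0, name="slow")
    spin = OscillatorSpec(0.98, 13.0, 100.0, 1.0, name="spindle")
    stat, _ = _stack_oscillators([slow, spin], (0, 1), q0_var=3.0)
    fitted, R, trace = sw.stationary_em(stat, y, 1.0, n_iter=50, update_initial=False)
    assert np.all(np.isfinite(trace))
    assert np.all(np.diff(trace) > -1e-6)
    for b in fitted.blocks:
        assert 0 < b.a <= 1 and 0 < b.sigma2 and np.isfinite(b.omega)
    # initial moments were held fixed
    np.testing.assert_array_equal(fitted.mu, stat.mu)
    np.testing.assert_array_equal(fitted.Q0, stat.Q0)
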