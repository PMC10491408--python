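"""Sufficient statistics, (tied) M-step updates and the VB-EM driver."""

import numpy as np
import pytest

import switchssm as sw
from switchssm.learning import EMConfig, expected_complete_loglik
from switchssm.model import TyingSpec
from switchssm.variational import EStepConfig

from conftest import random_R, random_ssm


def _estep_stats(model, y, **kw):
    res = sw.fixed_point_estep(model, y, EStepConfig(init_mode="interpolated", **kw))
    return res, sw.collect_stats(res.smoothers, res.post, y)


def _switching(rng, M=2, d=1, p=1):
    ssms = [random_ssm(rng, d, p) for _ in range(M)]
    rho = rng.dirichlet(np.ones(M))
    phi = rng.dirichlet(np.ones(M), size=M).T
    return sw.SwitchingModel(ssms, sw.MarkovChainParams(rho, phi), random_R(rng, p))


class TestCollectStats:
    def test_matches_naive_per_term_summation(self, rng):
        model = _switching(rng, M=2, d=2)
        sim = sw.simulate(model, 10, 1)
        res, stats = _estep_stats(model, sim.y)
        for m, sm in enumerate(res.smoothers):
            xs, Ps, Pl = sm.x_smooth, sm.P_smooth, sm.P_lag
            T = 10
            A = sum(Ps[t] + np.outer(xs[t], xs[t]) for t in range(T))
            B = sum(Pl[t] + np.outer(xs[t + 1], xs[t]) for t in range(T))
            C = sum(Ps[t] + np.outer(xs[t], xs[t]) for t in range(1, T + 1))
            st = stats.per_model[m]
            np.testing.assert_allclose(st.A, A, atol=1e-10)
            np.testing.assert_allclose(st.B, B, atol=1e-10)
            np.testing.assert_allclose(st.C, C, atol=1e-10)
            h = res.post.h[:, m]
            Sxx = sum(h[t] * (Ps[t + 1] + np.outer(xs[t + 1], xs[t + 1])) for t in range(T))
            np.testing.assert_allclose(st.Sxx_h, Sxx, atol=1e-10)
        np.testing.assert_allclose(stats.pair_sum, res.post.pairwise.sum(axis=0), atol=1e-12)

    def test_single_time_point_closed_form(self, rng):
        model = _switching(rng, M=1, d=1)
        y = rng.standard_normal((1, 1))
        res, stats = _estep_stats(model, y)
        sm = res.smoothers[0]
        st = stats.per_model[0]
        assert st.A.item() == pytest.approx(
            sm.P_smooth[0].item() + sm.x_smooth[0].item() ** 2, abs=1e-12
        )
        assert st.C.item() == pytest.approx(
            sm.P_smooth[1].item() + sm.x_smooth[1].item() ** 2, abs=1e-12
        )

    def test_single_model_reduces_to_classical_em_stats(self, rng):
        """With M = 1 (h = 1) the statistics are the Shumway-Stoffer ones."""
        model = _switching(rng, M=1, d=2)
        y = rng.standard_normal((12, 1))
        res, stats = _estep_stats(model, y)
        from switchssm.em import _single_stats

        filt = sw.kalman_filter(model.ssms[0], y, model.R)
        sm = sw.rts_smooth(model.ssms[0], filt)
        A, B, C, Syy, Syx, Sxx = _single_stats(sm, y)
        st = stats.per_model[0]
        np.testing.assert_allclose(st.A, A, atol=1e-10)
        np.testing.assert_allclose(st.B, B, atol=1e-10)
        np.testing.assert_allclose(st.Sxx_h, Sxx, atol=1e-10)


class TestMStep:
    def test_untied_single_model_matches_textbook_updates(self, rng):
        model = _switching(rng, M=1, d=2)
        y = rng.standard_normal((30, 1))
        res, stats = _estep_stats(model, y)
        new = sw.mstep(model, stats, EMConfig())
        st = stats.per_model[0]
        F = st.B @ np.linalg.inv(st.A)
        Q = (st.C - st.B @ F.T - F @ st.B.T + F @ st.A @ F.T) / 30
        np.testing.assert_allclose(new.ssms[0].F, F, atol=1e-10)
        np.testing.assert_allclose(new.ssms[0].Q, 0.5 * (Q + Q.T), atol=1e-10)
        np.testing.assert_allclose(new.ssms[0].mu, st.x0, atol=1e-12)
        np.testing.assert_allclose(new.ssms[0].Q0, st.P0, atol=1e-10)
        G = model.ssms[0].G
        R = (st.Syy_h - G @ st.Syx_h.T - st.Syx_h @ G.T + G @ st.Sxx_h @ G.T) / 30
        np.testing.assert_allclose(new.R, R, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_never_decreases_expected_complete_loglik(self, seed):
        rng = np.random.default_rng(seed)
        model = _switching(rng, M=2, d=2)
        sim = sw.simulate(model, 40, seed)
        res, stats = _estep_stats(model, sim.y)
        before = expected_complete_loglik(model, stats)
        after = expected_complete_loglik(sw.mstep(model, stats, EMConfig()), stats)
        assert after >= before - 1e-8

    def test_tied_update_never_decreases_and_respects_structure(self, rng):
        model = sw.make_bivariate_coupled()
        sim = sw.simulate_shared_state(model, 60, 4)
        res, stats = _estep_stats(model, sim.y)
        before = expected_complete_loglik(model, stats)
        new = sw.mstep(model, stats, EMConfig())
        assert expected_complete_loglik(new, stats) >= before - 1e-8
        F1, F2 = new.ssms[0].F, new.ssms[1].F
        assert F1[0, 0] == F2[0, 0] and F1[1, 1] == F2[1, 1]  # shared diagonal
        assert F2[0, 1] == 0.0 and F1[1, 0] == 0.0 and F2[1, 0] == 0.0  # structural zeros
        assert F1[0, 1] != 0.0  # the free coupling element
        np.testing.assert_array_equal(new.ssms[0].Q, new.ssms[1].Q)  # pooled Q

    def test_tied_solver_matches_numerical_optimum(self, rng):
        """The pooled normal equations solve the same problem as brute-force
        minimization of the expected complete log-likelihood over free F."""
        from scipy.optimize import minimize

        model = sw.make_bivariate_coupled()
        sim = sw.simulate_shared_state(model, 50, 9)
        res, stats = _estep_stats(model, sim.y)
        new = sw.mstep(model, stats, EMConfig(update_Q=False, update_R=False))

        def obj(theta):
            f11, f22, f12 = theta
            val = 0.0
            for m, st in enumerate(stats.per_model):
                F = np.array([[f11, f12 if m == 0 else 0.0], [0.0, f22]])
                Qi = np.linalg.inv(model.ssms[m].Q)
                S = st.C - st.B @ F.T - F @ st.B.T + F @ st.A @ F.T
                val += 0.5 * np.trace(Qi @ S)
            return val

        opt = minimize(obj, [0.4, 0.4, 0.4], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        f11, f22, f12 = opt.x
        assert new.ssms[0].F[0, 0] == pytest.approx(f11, abs=1e-5)
        assert new.ssms[0].F[1, 1] == pytest.approx(f22, abs=1e-5)
        assert new.ssms[0].F[0, 1] == pytest.approx(f12, abs=1e-5)

    def test_trivial_tying_dispatches_to_untied_path_bitwise(self, rng):
        model = _switching(rng, M=2, d=2)
        assert model.tying.is_trivial()
        sim = sw.simulate(model, 25, 2)
        res, stats = _estep_stats(model, sim.y)
        a = sw.mstep(model, stats, EMConfig())
        b = sw.mstep(model.copy(), stats, EMConfig())
        for sa, sb in zip(a.ssms, b.ssms):
            np.testing.assert_array_equal(sa.F, sb.F)
            np.testing.assert_array_equal(sa.Q, sb.Q)

    def test_update_flags_freeze_parameters(self, rng):
        model = _switching(rng, M=2, d=1)
        sim = sw.simulate(model, 20, 5)
        res, stats = _estep_stats(model, sim.y)
        new = sw.mstep(model, stats, EMConfig(
            update_mu=False, update_Q0=False, update_F=False, update_Q=False,
            update_R=False, update_rho=False, update_phi=False,
        ))
        for s_old, s_new in zip(model.ssms, new.ssms):
            np.testing.assert_array_equal(s_old.F, s_new.F)
            np.testing.assert_array_equal(s_old.mu, s_new.mu)
        np.testing.assert_array_equal(model.R, new.R)
        np.testing.assert_array_equal(model.chain.phi, new.chain.phi)


class TestVBEM:
    def test_learns_toward_truth_and_improves_segmentation(self, ar1_model):
        sim = sw.simulate(ar1_model, 300, 12)
        init = sw.make_ar1_switching(f_coefs=(0.95, 0.85), qs=(2.0, 6.0), r=0.15)
        fit = sw.vbem(init, sim.y, EStepConfig(init_mode="interpolated"), EMConfig())
        assert np.isfinite(fit.free_energy_trace).all()
        acc = sw.segmentation_accuracy(fit.varstate.h, sim.s)
        assert acc > 0.75
        # learned state-noise variances keep their identity (Q1 << Q2)
        assert fit.model.ssms[0].Q.item() < fit.model.ssms[1].Q.item()

    def test_chain_overestimates_self_transition_on_short_series(self):
        """Finite-sample bias: learned diagonal phi tends to exceed the true
        0.95 at T = 200."""
        truth = sw.make_ar1_switching(f_coefs=(0.90, 0.70), qs=(2.0, 10.0))
        diags = []
        for rep in range(20):
            sim = sw.simulate(truth, 200, 4000 + rep)
            rng = np.random.default_rng(4000 + rep)
            from switchssm.benchmarks import _draw_ar1_init

            fit = sw.vbem(_draw_ar1_init(rng), sim.y,
                          EStepConfig(init_mode="interpolated"), EMConfig())
            diags.append(0.5 * (fit.model.chain.phi[0, 0] + fit.model.chain.phi[1, 1]))
        assert np.mean(diags) > 0.95

    def test_parameter_error_shrinks_with_data_length(self):
        """Median |F_hat - F| decreases from T = 200 to T = 1000."""
        truth = sw.make_ar1_switching(f_coefs=(0.90, 0.70), qs=(2.0, 10.0))
        from switchssm.benchmarks import _draw_ar1_init

        errs = {200: [], 1000: []}
        for T in errs:
            for rep in range(8):
                sim = sw.simulate(truth, T, 7000 + rep)
                rng = np.random.default_rng(7000 + rep)
                fit = sw.vbem(_draw_ar1_init(rng), sim.y,
                              EStepConfig(init_mode="interpolated"), EMConfig())
                f = [fit.model.ssms[0].F.item(), fit.model.ssms[1].F.item()]
                errs[T].append(0.5 * (abs(f[0] - 0.90) + abs(f[1] - 0.70)))
        assert np.median(errs[1000]) < np.median(errs[200])

    def test_serialization_round_trip(self, rng, tmp_path):
        from switchssm.io import load_model, save_model

        model = sw.make_bivariate_coupled()
        save_model(model, tmp_path / "m.json", extra={"seed": 1})
        back = load_model(tmp_path / "m.json")
        np.testing.assert_array_equal(back.ssms[0].F, model.ssms[0].F)
        np.testing.assert_array_equal(back.R, model.R)
        assert back.tying.f_groups == model.tying.f_groups
        assert back.tying.q_groups == model.tying.q_groups
        sp = sw.build_spindle_model(
            sw.OscillatorSpec(0.98, 1.0, 100.0, name="slow"),
            sw.OscillatorSpec(0.98, 13.0, 100.0, name="spindle"), 1.0)
        save_model(sp, tmp_path / "sp.json")
        back = load_model(tmp_path / "sp.json")
        assert back.ssms[0].blocks[1].name == "spindle"
        assert back.tying.osc_groups == [[(0, 0), (1, 0)]]
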