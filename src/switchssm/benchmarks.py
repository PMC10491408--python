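"""Runners reproducing the simulation studies.

Each runner simulates ``reps`` independent sequences from the study's
generative model, applies the requested inference/learning methods and
returns a tidy table of per-repetition segmentation accuracies plus a
mean/SEM summary.  All generative parameters default to the study
conditions; a master seed spawns independent per-repetition seeds.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .baselines import imm, random_segmentation, static_switching
from .learning import EMConfig, vbem
from .metrics import segmentation_accuracy
from .model import SwitchingModel
from .models import (
    OscillatorSpec,
    build_nested_oscillator_models,
    make_ar1_switching,
    make_bivariate_coupled,
    oscillator_subsets,
)
from .simulate import simulate, simulate_shared_state, simulate_union_oscillators
from .variational import AnnealingSchedule, EStepConfig, fixed_point_estep

BENCHMARKS = ("ar1_inference", "ar1_learning", "bivariate", "oscillators")


def _spawn_seeds(seed, reps):
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(reps)]


def _estep_probs(model, y, mode, max_iter, anneal=None, center=None):
    cfg = EStepConfig(init_mode=mode, max_iter=max_iter, center_evidence=center)
    res = fixed_point_estep(model, y, cfg, anneal=anneal)
    return res.varstate.h


def run_ar1_inference(reps: int = 200, T: int = 200, seed: int = 0, n_iter: int = 12):
    """Two-AR(1) switching benchmark with true parameters known."""
    rows = []
    model = make_ar1_switching()
    anneal = AnnealingSchedule(100.0, n_iter)
    for rep, s in enumerate(_spawn_seeds(seed, reps)):
        sim = simulate(model, T, s)
        truth = sim.s
        res = {
            "vi_i": _estep_probs(model, sim.y, "interpolated", n_iter, center=False),
            "vi_a": _estep_probs(model, sim.y, "annealed", n_iter, anneal=anneal),
            "imm": imm(model, sim.y).probs,
            "static": static_switching(model, sim.y).probs,
            "random": random_segmentation(T, model.M, s + 1),
        }
        for method, est in res.items():
            rows.append((rep, method, segmentation_accuracy(est, truth)))
    return _finish(rows)


_AR1_LEARN_RANGES = {
    "f1": (0.8, 1.0), "f2": (0.6, 0.8), "q1": (1.0, 3.0), "q2": (5.0, 15.0),
    "r": (0.01, 0.2), "phi_diag": (0.9, 0.99),
}


def _draw_ar1_init(rng) -> SwitchingModel:
    u = {k: rng.uniform(*v) for k, v in _AR1_LEARN_RANGES.items()}
    return make_ar1_switching(
        f_coefs=(u["f1"], u["f2"]), qs=(u["q1"], u["q2"]), r=u["r"], phi_diag=u["phi_diag"]
    )


def run_ar1_learning(
    reps: int = 200, T: int = 200, seed: int = 0,
    n_anneal: int = 12, max_em_iter: int = 50,
):
    """AR(1) benchmark with unknown parameters learned by generalized EM.

    Initial parameters are drawn per sequence from uniform ranges centred at
    the truth; static switching and IMM use the drawn parameters as-is.
    """
    truth_model = make_ar1_switching(f_coefs=(0.90, 0.70), qs=(2.0, 10.0))
    anneal = AnnealingSchedule(100.0, n_anneal)
    mcfg = EMConfig(max_em_iter=max_em_iter)
    rows = []
    for rep, s in enumerate(_spawn_seeds(seed, reps)):
        rng = np.random.default_rng(s)
        sim = simulate(truth_model, T, s)
        init = _draw_ar1_init(rng)
        truth = sim.s
        fit_i = vbem(init, sim.y, EStepConfig(init_mode="interpolated", center_evidence=False), mcfg)
        fit_a = vbem(init, sim.y, EStepConfig(init_mode="annealed"), mcfg, anneal=anneal)
        res = {
            "vi_i_em": fit_i.varstate.h,
            "vi_a_em": fit_a.varstate.h,
            "imm": imm(init, sim.y).probs,
            "static": static_switching(init, sim.y).probs,
            "random": random_segmentation(T, 2, s + 1),
        }
        for method, est in res.items():
            rows.append((rep, method, segmentation_accuracy(est, truth)))
    return _finish(rows)


_BIV_RANGES = {"f": (0.4, 0.6), "q": (1.0, 3.0), "r": (0.01, 0.2), "phi_diag": (0.9, 0.99)}


def _draw_bivariate_init(rng) -> SwitchingModel:
    f11, f22, f12 = rng.uniform(*_BIV_RANGES["f"], size=3)
    q11, q22 = rng.uniform(*_BIV_RANGES["q"], size=2)
    r11, r22 = rng.uniform(*_BIV_RANGES["r"], size=2)
    phi_d = rng.uniform(*_BIV_RANGES["phi_diag"])
    model = make_bivariate_coupled(phi_diag=phi_d)
    for m, ssm in enumerate(model.ssms):
        ssm.F = np.array([[f11, f12 if m == 0 else 0.0], [0.0, f22]])
        ssm.Q = np.diag([q11, q22]).astype(float)
        ssm.Q0 = ssm.Q.copy()
    model.R = np.diag([r11, r22]).astype(float)
    return model


def run_bivariate(
    reps: int = 200, T: int = 200, seed: int = 0,
    learn: bool = True, learn_reps: Optional[int] = None,
    n_anneal: int = 12, max_em_iter: int = 50,
):
    """Coupled bivariate AR(1): switching F12 within a single shared state.

    True-parameter inference for all four methods; optionally VI-I EM
    learning with the shared-parameter (all-but-F12) tying.
    """
    model = make_bivariate_coupled()
    anneal = AnnealingSchedule(100.0, n_anneal)
    mcfg = EMConfig(max_em_iter=max_em_iter)
    rows = []
    learn_reps = reps if learn_reps is None else learn_reps
    for rep, s in enumerate(_spawn_seeds(seed, reps)):
        sim = simulate_shared_state(model, T, s)
        truth = sim.s
        res = {
            "vi_i": _estep_probs(model, sim.y, "interpolated", 50, center=False),
            "vi_a": _estep_probs(model, sim.y, "annealed", 50, anneal=anneal),
            "imm": imm(model, sim.y).probs,
            "static": static_switching(model, sim.y).probs,
            "random": random_segmentation(T, 2, s + 1),
        }
        if learn and rep < learn_reps:
            rng = np.random.default_rng(s)
            init = _draw_bivariate_init(rng)
            fit = vbem(init, sim.y, EStepConfig(init_mode="interpolated", center_evidence=False), mcfg)
            res["vi_i_em"] = fit.varstate.h
        for method, est in res.items():
            rows.append((rep, method, segmentation_accuracy(est, truth)))
    return _finish(rows)


def run_oscillators(
    reps: int = 200, seed: int = 0, n_range=(2, 3, 4, 5),
    duration_s: float = 10.0, fs: float = 100.0, max_iter: int = 12,
):
    """Nested-oscillator scaling study with true parameters.

    n oscillators at 1/10/20/30/40 Hz (a = 0.98, sigma2 = 3, R = 1) evolve
    continuously; the chain selects which nonempty subset is observed
    (2^n - 1 switching states).  VI-I (interpolated, mean-centred evidence)
    is compared with VI-A across n.
    """
    freqs = (1.0, 10.0, 20.0, 30.0, 40.0)
    T = int(round(duration_s * fs))
    rows = []
    for n in n_range:
        specs = [OscillatorSpec(0.98, f, fs, 3.0) for f in freqs[:n]]
        model = build_nested_oscillator_models(specs, 1.0, phi_diag=0.98)
        subsets = oscillator_subsets(n)
        anneal = AnnealingSchedule(100.0, max_iter)
        for rep, s in enumerate(_spawn_seeds(seed + 1000 * n, reps)):
            sim = simulate_union_oscillators(specs, subsets, model.chain, 1.0, T, s)
            truth = sim.s
            hi = _estep_probs(model, sim.y, "interpolated", max_iter, center=False)
            ha = _estep_probs(model, sim.y, "annealed", max_iter, anneal=anneal)
            rows.append((rep, f"vi_i_n{n}", segmentation_accuracy(hi, truth)))
            rows.append((rep, f"vi_a_n{n}", segmentation_accuracy(ha, truth)))
    return _finish(rows)


def _finish(rows):
    df = pd.DataFrame(rows, columns=["rep", "method", "accuracy"])
    summary = df.groupby("method")["accuracy"].agg(["mean", "sem", "count"])
    return df, summary


def run_benchmark(name: str, reps: int = 200, T: int = 200, seed: int = 0, **overrides):
    """Dispatch by study name; returns (per-rep DataFrame, summary table)."""
    if name == "ar1_inference":
        return run_ar1_inference(reps=reps, T=T, seed=seed, **overrides)
    if name == "ar1_learning":
        return run_ar1_learning(reps=reps, T=T, seed=seed, **overrides)
    if name == "bivariate":
        return run_bivariate(reps=reps, T=T, seed=seed, **overrides)
    if name == "oscillators":
        return run_oscillators(reps=reps, seed=seed, **overrides)
    raise ValueError(f"unknown benchmark {name!r}; choose from {BENCHMARKS}")
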