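"""Unsupervised sleep-spindle detection with switching oscillator models.

A two-candidate switching model (slow+spindle vs slow-only oscillators, slow
block tied) is fitted by variational EM with interpolated-density E-step
initialization and mean-centred evidence; the posterior probability of the
spindle-bearing candidate yields spindle events, and the smoothed oscillator
states yield the extracted slow and spindle waveforms with credible bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np
from scipy.signal import resample_poly

from .em import MapPriors, stationary_em
from .learning import EMConfig, vbem
from .model import SwitchingModel
from .models import OscillatorSpec, build_spindle_model, _stack_oscillators
from .variational import EStepConfig


@dataclass
class SpindleEvent:
    """One detected spindle with seconds-from-start margins."""

    onset_s: float
    offset_s: float
    peak_probability: float
    center_freq_hz: float
    mean_amplitude: float

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise ValueError("offset must follow onset")
        if not (0.0 <= self.peak_probability <= 1.0):
            raise ValueError("probability must lie in [0, 1]")


@dataclass
class RunConfig:
    """Spindle-detection pipeline settings."""

    target_fs: float = 100.0
    slow_init_hz: float = 1.0
    spindle_init_hz: float = 13.0
    init_a: float = 0.98
    init_sigma2: float = 1.0
    init_r: float = 1.0
    init_state_var: float = 3.0
    init_em_iters: int = 50
    phi_diag: float = 0.99
    threshold: float = 0.5
    min_duration_s: float = 0.3
    merge_gap_s: float = 0.1
    max_em_iter: int = 15
    em_f_rel_tol: float = 1e-5
    estep_max_iter: int = 25
    estep_h_tol: float = 1e-4
    sigma_band: tuple = (10.0, 17.0)
    min_damping: float = 0.85
    use_map_priors: bool = True
    priors: MapPriors = field(default_factory=MapPriors)
    seed: Optional[int] = None


def _resample(series, fs, target_fs):
    if fs == target_fs:
        return np.asarray(series, float)
    frac = Fraction(target_fs / fs).limit_denominator(1000)
    try:
        return resample_poly(np.asarray(series, float), frac.numerator, frac.denominator)
    except Exception as exc:  # pragma: no cover
        raise ValueError(f"cannot resample from {fs} to {target_fs} Hz") from exc


def _intervals_from_mask(mask, fs, min_duration_s, merge_gap_s):
    """Contiguous True runs as (onset_s, offset_s), merged and length-filtered."""
    idx = np.flatnonzero(np.diff(np.r_[0, mask.astype(int), 0]))
    runs = [(idx[i] / fs, idx[i + 1] / fs) for i in range(0, len(idx), 2)]
    merged = []
    for a, b in runs:
        if merged and a - merged[-1][1] <= merge_gap_s:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return [(a, b) for a, b in merged if b - a >= min_duration_s]


def fit_spindle_model(series, fs, cfg: RunConfig):
    """Oscillator initialization (stationary EM) followed by variational EM.

    Returns (fitted SwitchingModel, VBEMResult, resampled series).
    """
    x = _resample(series, fs, cfg.target_fs)
    fs = cfg.target_fs
    if x.size < 5 * fs:
        raise ValueError("series shorter than 5 s at the target sampling rate")
    if np.ptp(x) == 0:
        raise ValueError("constant input; nothing to model")
    slow0 = OscillatorSpec(cfg.init_a, cfg.slow_init_hz, fs, cfg.init_sigma2, name="slow")
    spin0 = OscillatorSpec(cfg.init_a, cfg.spindle_init_hz, fs, cfg.init_sigma2, name="spindle")
    stat, _ = _stack_oscillators([slow0, spin0], (0, 1), q0_var=cfg.init_state_var)
    priors = cfg.priors.bind(stat, fs) if cfg.use_map_priors else None
    fitted, r_fit, _ = stationary_em(
        stat, x, cfg.init_r, n_iter=cfg.init_em_iters, update_initial=False, priors=priors
    )
    slow_b, spin_b = fitted.blocks
    if slow_b.omega > spin_b.omega:
        slow_b, spin_b = spin_b, slow_b
    slow = OscillatorSpec(slow_b.a, slow_b.omega * fs / (2 * np.pi), fs, slow_b.sigma2, name="slow")
    spin = OscillatorSpec(spin_b.a, spin_b.omega * fs / (2 * np.pi), fs, spin_b.sigma2, name="spindle")
    model = build_spindle_model(slow, spin, float(np.asarray(r_fit).item()), phi_diag=cfg.phi_diag,
                                q0_var=cfg.init_state_var)
    mpriors = priors.bind(model.ssms[0], fs) if cfg.use_map_priors else None
    mcfg = EMConfig(
        max_em_iter=cfg.max_em_iter, f_rel_tol=cfg.em_f_rel_tol,
        update_mu=False, update_Q0=False, priors=mpriors,
    )
    ecfg = EStepConfig(
        init_mode="interpolated", max_iter=cfg.estep_max_iter, h_tol=cfg.estep_h_tol
    )
    fit = vbem(model, x, ecfg, mcfg)
    return fit.model, fit, x


def detect_spindles(series, fs, cfg: Optional[RunConfig] = None):
    """Full pipeline: resample, initialize, fit, threshold, extract waveforms.

    Returns (events, per-sample spindle probabilities, waveforms dict, fitted
    model).  Waveforms carry the smoothed slow/spindle real parts with
    +-1.96 posterior-SD bands.
    """
    cfg = cfg or RunConfig()
    model, fit, x = fit_spindle_model(series, fs, cfg)
    fs_t = cfg.target_fs
    probs = fit.varstate.h[:, 0]
    spin_blk = model.ssms[0].blocks[1]
    f_hz = spin_blk.omega * fs_t / (2 * np.pi)
    # a spindle must be an identifiable sigma-band oscillation: the learned
    # component has to be narrowband (damping close to 1) and inside the
    # sigma range, otherwise the richer candidate is just absorbing noise
    is_sigma = (cfg.sigma_band[0] <= f_hz <= cfg.sigma_band[1]) and spin_blk.a >= cfg.min_damping
    mask = (probs >= cfg.threshold) if is_sigma else np.zeros_like(probs, dtype=bool)
    intervals = _intervals_from_mask(mask, fs_t, cfg.min_duration_s, cfg.merge_gap_s)
    sm = fit.estep.smoothers[0]
    xs = sm.x_smooth[1:]
    sd = np.sqrt(np.maximum(np.diagonal(sm.P_smooth[1:], axis1=1, axis2=2), 0.0))
    waveforms = {
        "t": np.arange(x.size) / fs_t,
        "slow_mean": xs[:, 0], "slow_lo": xs[:, 0] - 1.96 * sd[:, 0], "slow_hi": xs[:, 0] + 1.96 * sd[:, 0],
        "spindle_mean": xs[:, 2], "spindle_lo": xs[:, 2] - 1.96 * sd[:, 2], "spindle_hi": xs[:, 2] + 1.96 * sd[:, 2],
        "spindle_imag": xs[:, 3],
    }
    events = []
    amp = np.hypot(xs[:, 2], xs[:, 3])
    for a, b in intervals:
        i0, i1 = int(round(a * fs_t)), int(round(b * fs_t))
        events.append(
            SpindleEvent(
                onset_s=a, offset_s=b,
                peak_probability=float(probs[i0:i1].max()),
                center_freq_hz=float(f_hz),
                mean_amplitude=float(amp[i0:i1].mean()),
            )
        )
    return events, probs, waveforms, model


def synthesize_sleep_eeg(
    duration_s: float = 30.0,
    fs: float = 100.0,
    slow: Optional[OscillatorSpec] = None,
    spindle: Optional[OscillatorSpec] = None,
    density_per_min: float = 6.0,
    duration_range=(0.5, 3.0),
    r: float = 1.0,
    seed=None,
):
    """Synthetic NREM-like EEG: continuous slow oscillation plus transient spindles.

    Both oscillators evolve for the whole record; spindles are observed only
    inside events whose count is Poisson with the given per-minute density and
    whose durations are uniform over ``duration_range`` (the sigma-band burst
    length range).  Returns (series, true spindle intervals in seconds).
    """
    if density_per_min < 0:
        raise ValueError("density must be non-negative")
    rng = np.random.default_rng(seed)
    slow = slow or OscillatorSpec(0.99, 1.0, fs, 3.0, name="slow")
    spindle = spindle or OscillatorSpec(0.95, 13.0, fs, 3.0, name="spindle")
    T = int(round(duration_s * fs))
    n_events = rng.poisson(density_per_min * duration_s / 60.0)
    intervals = []
    for _ in range(n_events):
        for _attempt in range(100):
            dur = rng.uniform(*duration_range)
            onset = rng.uniform(0.0, max(duration_s - dur, 0.0))
            if all(onset + dur <= a or onset >= b for a, b in intervals):
                intervals.append((onset, onset + dur))
                break
    intervals.sort()
    mask = np.zeros(T, dtype=bool)
    for a, b in intervals:
        mask[int(round(a * fs)): int(round(b * fs))] = True
    from .em import rotation

    Fs_ = [rotation(s.a, s.omega) for s in (slow, spindle)]
    x = np.empty((T + 1, 4))
    x[0, :2] = np.sqrt(slow.sigma2) * rng.standard_normal(2)
    x[0, 2:] = np.sqrt(spindle.sigma2) * rng.standard_normal(2)
    y = np.empty(T)
    sr = np.sqrt(r)
    for t in range(1, T + 1):
        x[t, :2] = Fs_[0] @ x[t - 1, :2] + np.sqrt(slow.sigma2) * rng.standard_normal(2)
        x[t, 2:] = Fs_[1] @ x[t - 1, 2:] + np.sqrt(spindle.sigma2) * rng.standard_normal(2)
        y[t - 1] = x[t, 0] + (x[t, 2] if mask[t - 1] else 0.0) + sr * rng.standard_normal()
    return y, intervals


def event_recall(true_intervals, events, iou_min: float = 0.3) -> float:
    """Fraction of true intervals overlapped by a detection at IoU >= iou_min."""
    if not true_intervals:
        return float("nan")
    hit = 0
    for a, b in true_intervals:
        best = 0.0
        for ev in events:
            inter = max(0.0, min(b, ev.offset_s) - max(a, ev.onset_s))
            union = max(b, ev.offset_s) - min(a, ev.onset_s)
            best = max(best, inter / union)
        hit += best >= iou_min
    return hit / len(true_intervals)
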