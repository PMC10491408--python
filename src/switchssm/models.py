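"""Model builders: AR(1) candidates, state-space oscillators, nested oscillator
sets and the two-candidate sleep-spindle model."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .em import rotation
from .hmm import MarkovChainParams
from .model import SwitchingModel, TyingSpec
from .ssm import GaussianSSM, OscillatorBlock


@dataclass
class OscillatorSpec:
    """Damped-rotation oscillator: damping a, frequency f_hz at sampling rate fs,
    isotropic state-noise variance sigma2."""

    a: float
    f_hz: float
    fs: float
    sigma2: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.a <= 1):
            raise ValueError("damping a must lie in (0, 1]")
        if not (0 <= self.f_hz < self.fs / 2):
            raise ValueError(f"frequency {self.f_hz} Hz aliases at fs={self.fs} Hz")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    @property
    def omega(self) -> float:
        """Rotation frequency in radians per sample."""
        return 2.0 * np.pi * self.f_hz / self.fs


def make_ar1(f_coef: float, q: float, mu: float = 0.0, q0: float | None = None) -> GaussianSSM:
    """Scalar AR(1) candidate x_t = f x_{t-1} + w, w ~ N(0, q), observed directly."""
    if q <= 0:
        raise ValueError("state-noise variance q must be positive")
    if abs(f_coef) >= 1:
        warnings.warn("|f| >= 1: non-stationary AR coefficient", stacklevel=2)
    if q0 is None:
        q0 = q
    return GaussianSSM(
        mu=[mu], Q0=[[q0]], F=[[f_coef]], Q=[[q]], G=[[1.0]]
    )


def make_oscillator(spec: OscillatorSpec, start: int = 0) -> GaussianSSM:
    """2-D phasor a*Rot(omega) with Q = sigma2*I2 and G = [1 0]."""
    blk = OscillatorBlock(spec.name or f"{spec.f_hz:g}Hz", spec.a, spec.omega, spec.sigma2, start)
    return GaussianSSM(
        mu=np.zeros(2),
        Q0=spec.sigma2 * np.eye(2),
        F=rotation(spec.a, spec.omega),
        Q=spec.sigma2 * np.eye(2),
        G=[[1.0, 0.0]],
        blocks=[blk],
    )


def _stack_oscillators(specs, subset, q0_var=None):
    """Candidate model stacking the oscillator blocks listed in ``subset``."""
    d = 2 * len(subset)
    F = np.zeros((d, d))
    Q = np.zeros((d, d))
    Q0 = np.zeros((d, d))
    G = np.zeros((1, d))
    blocks = []
    union_idx = []
    for k, j in enumerate(subset):
        sp = specs[j]
        sl = slice(2 * k, 2 * k + 2)
        F[sl, sl] = rotation(sp.a, sp.omega)
        Q[sl, sl] = sp.sigma2 * np.eye(2)
        Q0[sl, sl] = (q0_var if q0_var is not None else sp.sigma2) * np.eye(2)
        G[0, 2 * k] = 1.0
        blocks.append(OscillatorBlock(sp.name or f"{sp.f_hz:g}Hz", sp.a, sp.omega, sp.sigma2, 2 * k))
        union_idx.extend([2 * j, 2 * j + 1])
    return GaussianSSM(np.zeros(d), Q0, F, Q, G, blocks=blocks), np.array(union_idx)


def oscillator_subsets(n: int):
    """Nonempty subsets of n oscillators ordered by size then lexicographically."""
    out = []
    for size in range(1, n + 1):
        out.extend(itertools.combinations(range(n), size))
    return out


def build_nested_oscillator_models(specs, R, phi_diag: float = 0.98, q0_var=None) -> SwitchingModel:
    """All 2^n - 1 nonempty oscillator combinations as candidate models.

    Candidate k observes the sum of the real parts of its oscillators
    (concatenated G = [1 0 1 0 ...]); the chain has uniform initial
    probabilities and a symmetric transition matrix with ``phi_diag`` on the
    diagonal.
    """
    n = len(specs)
    if not (1 <= n <= 5):
        raise ValueError("between 1 and 5 oscillators supported (2^n - 1 candidates)")
    subsets = oscillator_subsets(n)
    ssms, state_blocks = [], []
    for sub in subsets:
        ssm, union_idx = _stack_oscillators(specs, sub, q0_var)
        ssms.append(ssm)
        state_blocks.append(union_idx)
    M = len(subsets)
    rho = np.full(M, 1.0 / M)
    phi = np.full((M, M), (1.0 - phi_diag) / (M - 1)) if M > 1 else np.ones((1, 1))
    if M > 1:
        np.fill_diagonal(phi, phi_diag)
    return SwitchingModel(
        ssms, MarkovChainParams(rho, phi), R, state_blocks=state_blocks
    )


def build_spindle_model(
    slow: OscillatorSpec,
    spindle: OscillatorSpec,
    r: float,
    phi_diag: float = 0.99,
    q0_var: float = 3.0,
) -> SwitchingModel:
    """Two-candidate spindle model: slow+spindle vs slow only, slow block tied.

    Model 1 stacks the slow and spindle oscillators (G = [1 0 1 0]); model 2
    contains only the slow oscillator (G = [1 0]).  The slow block's
    (a, omega, sigma2) are shared across the two candidates during learning.
    """
    if not slow.f_hz < spindle.f_hz:
        raise ValueError("slow oscillator frequency must be below the spindle frequency")
    slow = OscillatorSpec(slow.a, slow.f_hz, slow.fs, slow.sigma2, name="slow")
    spindle = OscillatorSpec(spindle.a, spindle.f_hz, spindle.fs, spindle.sigma2, name="spindle")
    m1, _ = _stack_oscillators([slow, spindle], (0, 1), q0_var)
    m2, _ = _stack_oscillators([slow], (0,), q0_var)
    chain = MarkovChainParams([0.5, 0.5], [[phi_diag, 1 - phi_diag], [1 - phi_diag, phi_diag]])
    tying = TyingSpec(osc_groups=[[(0, 0), (1, 0)]])
    return SwitchingModel(
        [m1, m2], chain, r, tying=tying,
        state_blocks=[np.arange(4), np.arange(2)],
    )


def make_ar1_switching(
    f_coefs=(0.99, 0.90), qs=(1.0, 10.0), r: float = 0.1,
    phi_diag: float = 0.95, rho=(0.5, 0.5),
) -> SwitchingModel:
    """Two-AR(1) switching benchmark model (observation y_t = x_t^{(s_t)} + v_t)."""
    ssms = [make_ar1(f, q) for f, q in zip(f_coefs, qs)]
    M = len(ssms)
    phi = np.full((M, M), (1 - phi_diag) / (M - 1)) if M > 1 else np.ones((1, 1))
    if M > 1:
        np.fill_diagonal(phi, phi_diag)
    return SwitchingModel(ssms, MarkovChainParams(np.asarray(rho, float), phi), r)


def make_bivariate_coupled(
    f_diag: float = 0.5, f12: float = 0.5, q: float = 2.0, r: float = 0.1,
    phi_diag: float = 0.95,
) -> SwitchingModel:
    """Two 2-D candidates differing only in the coupling element F12 (f12 vs 0).

    The second sequence drives the first when the switch is in state 1; the
    tying spec shares every free dynamics parameter across candidates except
    F12 of model 1 (F21 and F12 of model 2 are structural zeros).
    """
    def ssm(f12_val):
        F = np.array([[f_diag, f12_val], [0.0, f_diag]])
        Q = q * np.eye(2)
        return GaussianSSM(np.zeros(2), Q.copy(), F, Q, np.eye(2))

    chain = MarkovChainParams(
        [0.5, 0.5], [[phi_diag, 1 - phi_diag], [1 - phi_diag, phi_diag]]
    )
    free = [
        np.array([[True, True], [False, True]]),
        np.array([[True, False], [False, True]]),
    ]
    tying = TyingSpec(
        f_groups=[[(0, 0, 0), (1, 0, 0)], [(0, 1, 1), (1, 1, 1)]],
        f_free=free,
        q_groups=[[0, 1]],
    )
    return SwitchingModel([ssm(f12), ssm(0.0)], chain, r * np.eye(2), tying=tying)
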