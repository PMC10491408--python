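"""Switching-model container and parameter-tying specification."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .hmm import MarkovChainParams
from .ssm import GaussianSSM, _as_R


@dataclass
class TyingSpec:
    """Parameter blocks shared across candidate models.

    f_groups
        Groups of F elements sharing one value; each group is a list of
        (model, row, col) entries.  Elements listed in ``f_free`` but in no
        group are singletons (updated independently).
    f_free
        Per-model boolean masks of F entries that are updated; entries outside
        the mask keep their current value (e.g. structural zeros).  ``None``
        means every entry of every F is free.
    q_groups
        Groups of model indices sharing a single state-noise covariance Q.
    osc_groups
        Groups of (model, block) oscillator blocks sharing (a, omega, sigma2);
        used for oscillator-structured models.
    shared_r
        Whether a single observation-noise covariance R is pooled across
        models (the default) or each model keeps its own.
    """

    f_groups: list[list[tuple[int, int, int]]] = field(default_factory=list)
    f_free: Optional[list[np.ndarray]] = None
    q_groups: list[list[int]] = field(default_factory=list)
    osc_groups: list[list[tuple[int, int]]] = field(default_factory=list)
    shared_r: bool = True

    def is_trivial(self) -> bool:
        return (
            not self.f_groups
            and self.f_free is None
            and not self.q_groups
            and not self.osc_groups
        )


@dataclass
class SwitchingModel:
    """M parallel Gaussian SSMs selected per time step by a hidden Markov chain.

    All candidates share the observation dimension p and (by default) a single
    observation-noise covariance R.  ``state_blocks`` optionally maps each
    candidate's state coordinates into a common union state (set by the nested
    oscillator builders); baselines that mix states across models of unequal
    dimension require it.
    """

    ssms: list[GaussianSSM]
    chain: MarkovChainParams
    R: np.ndarray
    tying: TyingSpec = field(default_factory=TyingSpec)
    state_blocks: Optional[list[np.ndarray]] = None

    def __post_init__(self) -> None:
        if len(self.ssms) < 1:
            raise ValueError("need at least one candidate model")
        p = self.ssms[0].p
        if any(s.p != p for s in self.ssms):
            raise ValueError("all candidate models must share the observation dimension")
        if self.chain.M != len(self.ssms):
            raise ValueError("chain size must match the number of candidate models")
        self.R = _as_R(self.R, p)
        if self.state_blocks is not None:
            self.state_blocks = [np.asarray(b, dtype=int) for b in self.state_blocks]
            for s, b in zip(self.ssms, self.state_blocks):
                if b.shape[0] != s.d:
                    raise ValueError("state_blocks entries must index every state coordinate")

    @property
    def M(self) -> int:
        return len(self.ssms)

    @property
    def p(self) -> int:
        return self.ssms[0].p

    @property
    def dims(self) -> list[int]:
        return [s.d for s in self.ssms]

    def copy(self) -> "SwitchingModel":
        import copy as _copy

        return SwitchingModel(
            [s.copy() for s in self.ssms],
            MarkovChainParams(self.chain.rho.copy(), self.chain.phi.copy()),
            self.R.copy(),
            tying=_copy.deepcopy(self.tying),
            state_blocks=None if self.state_blocks is None
            else [b.copy() for b in self.state_blocks],
        )
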