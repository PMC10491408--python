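"""Readers/writers: numeric series from CSV (or EDF via mne), model JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .hmm import MarkovChainParams
from .model import SwitchingModel, TyingSpec
from .ssm import GaussianSSM, OscillatorBlock


def read_series(path, fs: float | None = None, channel: str | None = None):
    """Read a single-channel series; returns (values, fs).

    CSV with one column requires ``fs``; CSV with (time, value) columns infers
    the rate from the time stamps; ``.edf`` files are read through mne
    (optional dependency) selecting ``channel`` by label.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise ImportError("reading EDF requires the optional dependency mne") from exc
        raw = mne.io.read_raw_edf(path, include=[channel] if channel else None, preload=True, verbose="error")
        data = raw.get_data()[0]
        return np.asarray(data, float), float(raw.info["sfreq"])
    df = pd.read_csv(path, header=None)
    if df.shape[1] == 1:
        if fs is None:
            raise ValueError("single-column CSV requires a sampling rate (fs)")
        return df.iloc[:, 0].to_numpy(float), float(fs)
    if df.shape[1] == 2:
        t = df.iloc[:, 0].to_numpy(float)
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time column is not uniformly sampled")
        return df.iloc[:, 1].to_numpy(float), float(1.0 / dt[0])
    raise ValueError("expected a one- or two-column CSV")


def _arr(x):
    return np.asarray(x).tolist()


def model_to_dict(model: SwitchingModel) -> dict:
    out = {
        "ssms": [
            {
                "mu": _arr(s.mu), "Q0": _arr(s.Q0), "F": _arr(s.F), "Q": _arr(s.Q),
                "G": _arr(s.G),
                "blocks": None if s.blocks is None else [
                    {"name": b.name, "a": b.a, "omega": b.omega, "sigma2": b.sigma2, "start": b.start}
                    for b in s.blocks
                ],
            }
            for s in model.ssms
        ],
        "chain": {"rho": _arr(model.chain.rho), "phi": _arr(model.chain.phi)},
        "R": _arr(model.R),
        "tying": {
            "f_groups": [[list(e) for e in grp] for grp in model.tying.f_groups],
            "f_free": None if model.tying.f_free is None else [_arr(m) for m in model.tying.f_free],
            "q_groups": [list(g) for g in model.tying.q_groups],
            "osc_groups": [[list(e) for e in grp] for grp in model.tying.osc_groups],
            "shared_r": model.tying.shared_r,
        },
        "state_blocks": None if model.state_blocks is None else [_arr(b) for b in model.state_blocks],
    }
    return out


def model_from_dict(d: dict) -> SwitchingModel:
    ssms = []
    for s in d["ssms"]:
        blocks = None
        if s.get("blocks"):
            blocks = [OscillatorBlock(b["name"], b["a"], b["omega"], b["sigma2"], b["start"]) for b in s["blocks"]]
        ssms.append(GaussianSSM(s["mu"], s["Q0"], s["F"], s["Q"], s["G"], blocks=blocks))
    ty = d.get("tying", {})
    tying = TyingSpec(
        f_groups=[[tuple(e) for e in grp] for grp in ty.get("f_groups", [])],
        f_free=None if ty.get("f_free") is None else [np.asarray(m, bool) for m in ty["f_free"]],
        q_groups=[list(g) for g in ty.get("q_groups", [])],
        osc_groups=[[tuple(e) for e in grp] for grp in ty.get("osc_groups", [])],
        shared_r=ty.get("shared_r", True),
    )
    return SwitchingModel(
        ssms,
        MarkovChainParams(d["chain"]["rho"], d["chain"]["phi"]),
        np.asarray(d["R"], float),
        tying=tying,
        state_blocks=None if d.get("state_blocks") is None else [np.asarray(b, int) for b in d["state_blocks"]],
    )


def save_model(model: SwitchingModel, path, extra: dict | None = None) -> None:
    doc = model_to_dict(model)
    if extra:
        doc["meta"] = extra
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path) -> SwitchingModel:
    return model_from_dict(json.loads(Path(path).read_text()))
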