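"""Segmentation metrics."""

from __future__ import annotations

import itertools

import numpy as np


def labels_from_probs(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard labels from (T, M) probabilities: 0.5 threshold on column 0 for
    two models, argmax otherwise."""
    probs = np.asarray(probs)
    if probs.ndim == 1:
        return probs.astype(int)
    if probs.shape[1] == 2:
        return np.where(probs[:, 0] >= threshold, 0, 1)
    return probs.argmax(axis=1)


def segmentation_accuracy(
    est, truth, threshold: float = 0.5, permute: bool = False
) -> float:
    """Fraction of time points whose estimated switch label matches the truth.

    ``est`` may be hard labels (T,) or probabilities (T, M).  With ``permute``
    the best label permutation is used (for label-unidentified fits).
    """
    truth = np.asarray(truth, dtype=int)
    est = np.asarray(est)
    labels = labels_from_probs(est, threshold) if est.ndim == 2 else est.astype(int)
    if labels.shape != truth.shape:
        raise ValueError("estimate and truth must have equal length")
    if not permute:
        return float((labels == truth).mean())
    M = int(max(labels.max(), truth.max())) + 1
    best = 0.0
    for perm in itertools.permutations(range(M)):
        mapped = np.asarray(perm)[labels]
        best = max(best, float((mapped == truth).mean()))
    return best
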