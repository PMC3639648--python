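"""Pixel-classification scoring against a ground-truth vessel mask.

Inside the field of view (all pixels when no FOV mask is given):

    SE = N_correct_vessel / N_vessel          (sensitivity)
    SP = N_correct_nonvessel / N_nonvessel    (specificity)
    AC = N_correct_total / N_total            (accuracy)

Accuracy is the prevalence-weighted combination of SE and SP:
AC = (N_vessel * SE + N_nonvessel * SP) / N_total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel counts of the binary confusion table over the FOV."""

    n_correct_vessel: int
    n_vessel: int
    n_correct_nonvessel: int
    n_nonvessel: int
    n_correct_total: int
    n_total: int


def confusion(pred: np.ndarray, truth: np.ndarray,
              fov: Optional[np.ndarray] = None) -> ConfusionCounts:
    """Count agreements between a predicted and a truth mask over the FOV."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if fov is not None:
        fov = np.asarray(fov, dtype=bool)
        if fov.shape != pred.shape:
            raise ValueError(f"FOV shape mismatch: {fov.shape}")
        pred, truth = pred[fov], truth[fov]
    tp = int(np.count_nonzero(pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    nv = int(np.count_nonzero(truth))
    nn = truth.size - nv
    return ConfusionCounts(
        n_correct_vessel=tp, n_vessel=nv,
        n_correct_nonvessel=tn, n_nonvessel=nn,
        n_correct_total=tp + tn, n_total=truth.size,
    )


def metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(SE, SP, AC) from confusion counts; an empty class yields NaN for
    its ratio with a warning."""
    if counts.n_vessel > 0:
        se = counts.n_correct_vessel / counts.n_vessel
    else:
        warnings.warn("no vessel pixels in truth; SE undefined")
        se = float("nan")
    if counts.n_nonvessel > 0:
        sp = counts.n_correct_nonvessel / counts.n_nonvessel
    else:
        warnings.warn("no non-vessel pixels in truth; SP undefined")
        sp = float("nan")
    ac = counts.n_correct_total / counts.n_total if counts.n_total else float("nan")
    return se, sp, ac
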