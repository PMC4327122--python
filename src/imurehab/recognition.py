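"""Apply a trained network to unlabeled windows and score recognition rates.

Each input column produces a 6-row column of recognition indices in
[0, 1]; the row with the largest index names the recognized exercise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bpnn import NetworkModel, forward
from .features import INPUT_LENGTH, N_EXERCISES

log = logging.getLogger(__name__)

__all__ = ["RecognitionInput", "recognize", "decode", "recognition_rate"]


@dataclass(frozen=True)
class RecognitionInput:
    """An 800 x n matrix of unlabeled window columns, optionally with truth."""

    values: np.ndarray  # (800, n)
    true_labels: np.ndarray | None = None  # (n,), 1-based

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.shape[0] != INPUT_LENGTH:
            raise ValueError(f"recognition input must have {INPUT_LENGTH} rows")
        if self.true_labels is not None and len(self.true_labels) != self.values.shape[1]:
            raise ValueError("true_labels length must match column count")


def recognize(model: NetworkModel, inp: RecognitionInput | np.ndarray) -> np.ndarray:
    """Forward every column through the model; clamp indices into [0, 1].

    The linear output layer can stray outside [0, 1]; clamping honors the
    documented index bounds without changing the argmax.
    """
    if model.stop_reason == "untrained":
        raise ValueError("model has not been trained")
    X = inp.values if isinstance(inp, RecognitionInput) else np.asarray(inp, dtype=float)
    if X.ndim != 2 or X.shape[0] != model.sizes[0]:
        raise ValueError(f"recognition input must have {model.sizes[0]} rows")
    return np.clip(forward(model, X), 0.0, 1.0)


def decode(result: np.ndarray) -> np.ndarray:
    """Exercise label (1-based) per column: argmax over the six index rows.

    Ties break toward the lowest exercise index with a logged warning.
    """
    R = np.asarray(result, dtype=float)
    if R.ndim != 2 or R.shape[0] != N_EXERCISES:
        raise ValueError(f"result matrix must have {N_EXERCISES} rows")
    labels = R.argmax(axis=0) + 1  # np.argmax already takes the first maximum
    n_tied = int((np.sum(R == R.max(axis=0, keepdims=True), axis=0) > 1).sum())
    if n_tied:
        log.warning("%d columns had tied recognition indices; lowest exercise kept", n_tied)
    return labels


def recognition_rate(decoded: np.ndarray, truth: np.ndarray) -> tuple[dict[int, float], float]:
    """Per-exercise and overall fraction of correctly decoded windows.

    An exercise absent from the truth gets NaN (not 0), mirroring blind
    tests in which a participant skips exercises.
    """
    decoded = np.asarray(decoded)
    truth = np.asarray(truth)
    if decoded.shape != truth.shape:
        raise ValueError("decoded and true label arrays must have equal length")
    per_class: dict[int, float] = {}
    for k in range(1, N_EXERCISES + 1):
        mask = truth == k
        per_class[k] = float(np.mean(decoded[mask] == k)) if mask.any() else float("nan")
    overall = float(np.mean(decoded == truth)) if len(truth) else float("nan")
    return per_class, overall
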