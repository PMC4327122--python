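"""Included-angle feature, overlapping window assembly and training matrices.

The classifier input is built from four per-tick feature streams — the
three acceleration components plus the included angle between consecutive
acceleration vectors — cut into 25-s windows of 200 ticks at 8 ticks/s.
Consecutive windows share one quarter of their length (stride 150 ticks).
Each window flattens to an 800-long vector: 200 values of ``a_x``, then
``a_y``, ``a_z``, then the angle stream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .packet_io import CalibratedSample, samples_to_array

log = logging.getLogger(__name__)

RATE_HZ = 8.0
WINDOW_SECONDS = 25.0
WINDOW_TICKS = 200  # 25 s * 8/s
STRIDE_TICKS = 150  # three quarters of a window
FEATURE_NAMES = ("ax", "ay", "az", "theta")
N_FEATURES = 4
INPUT_LENGTH = WINDOW_TICKS * N_FEATURES  # 800
N_EXERCISES = 6

__all__ = [
    "RATE_HZ",
    "WINDOW_TICKS",
    "STRIDE_TICKS",
    "FEATURE_NAMES",
    "N_FEATURES",
    "INPUT_LENGTH",
    "N_EXERCISES",
    "MotionWindow",
    "DegenerateVectorError",
    "ShortageError",
    "included_angle",
    "angle_series",
    "make_windows",
    "build_matrices",
    "stack_cells",
    "FeatureScaler",
]


class DegenerateVectorError(ValueError):
    """Zero-length vector passed where a direction is required."""


class ShortageError(ValueError):
    """An exercise supplied fewer windows than requested."""


@dataclass(frozen=True)
class MotionWindow:
    """One flattened 800-value data entry, optionally labeled 1..6."""

    values: np.ndarray  # (800,)
    label: int | None = None
    start_time: float = 0.0

    def __post_init__(self):
        if self.values.shape != (INPUT_LENGTH,):
            raise ValueError(f"window must hold {INPUT_LENGTH} values, got {self.values.shape}")
        theta = self.feature("theta")
        if (theta < -1e-9).any() or (theta > 180.0 + 1e-9).any():
            raise ValueError("theta entries must lie in [0, 180] degrees")
        if self.label is not None and not 1 <= self.label <= N_EXERCISES:
            raise ValueError(f"label must be 1..{N_EXERCISES}")

    def feature(self, name: str) -> np.ndarray:
        """Return one 200-value feature block by name."""
        i = FEATURE_NAMES.index(name)
        return self.values[i * WINDOW_TICKS : (i + 1) * WINDOW_TICKS]


def included_angle(a1, a2) -> float:
    """Angle in degrees between two 3-vectors via the normalized dot product.

    Clamped into [0, 180] against floating-point overflow of the cosine.
    Raises :class:`DegenerateVectorError` for a zero vector.
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    n1 = np.linalg.norm(a1)
    n2 = np.linalg.norm(a2)
    if n1 == 0.0 or n2 == 0.0:
        raise DegenerateVectorError("included angle undefined for a zero vector")
    c = np.clip(np.dot(a1, a2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def angle_series(samples) -> np.ndarray:
    """Per-tick included angle between consecutive acceleration vectors.

    Accepts a sequence of :class:`CalibratedSample` or an (n, 3) array.  The
    raw series has n-1 angles; it is padded at the start by repeating the
    first value so the stream stays aligned with the other features.  Zero
    vectors yield 0 degrees with a logged warning (bulk processing must not
    abort on a degenerate tick).
    """
    if len(samples) and isinstance(samples[0], CalibratedSample):
        _, acc, _ = samples_to_array(samples)
    else:
        acc = np.asarray(samples, dtype=float)
    if acc.ndim != 2 or acc.shape[1] != 3:
        raise ValueError("expected an (n, 3) acceleration array")
    n = acc.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples for an angle series")
    norms = np.linalg.norm(acc, axis=1)
    zero = norms == 0.0
    if zero.any():
        log.warning("%d zero acceleration vectors; their angles set to 0", int(zero.sum()))
    safe = np.where(zero, 1.0, norms)
    dots = np.einsum("ij,ij->i", acc[:-1], acc[1:])
    cosines = np.clip(dots / (safe[:-1] * safe[1:]), -1.0, 1.0)
    theta = np.degrees(np.arccos(cosines))
    theta[zero[:-1] | zero[1:]] = 0.0
    return np.concatenate(([theta[0]], theta))


def make_windows(samples, label: int | None = None) -> list[MotionWindow]:
    """Cut a sample stream into overlapping flattened windows.

    Windows are 200 ticks long with stride 150 (the last quarter of each
    window is the first quarter of the next); a trailing partial window is
    discarded.  Fewer than 200 samples yield an empty list with a warning.
    """
    if len(samples) and isinstance(samples[0], CalibratedSample):
        t, acc, _ = samples_to_array(samples)
    else:
        acc = np.asarray(samples, dtype=float)
        t = np.arange(len(acc)) / RATE_HZ
    n = acc.shape[0]
    if n < WINDOW_TICKS:
        warnings.warn(f"only {n} samples (< {WINDOW_TICKS}); no windows produced", stacklevel=2)
        return []
    theta = angle_series(acc)
    streams = (acc[:, 0], acc[:, 1], acc[:, 2], theta)
    windows = []
    for start in range(0, n - WINDOW_TICKS + 1, STRIDE_TICKS):
        blocks = [s[start : start + WINDOW_TICKS] for s in streams]
        windows.append(
            MotionWindow(values=np.concatenate(blocks), label=label, start_time=float(t[start]))
        )
    return windows


def build_matrices(
    windows_by_exercise: dict[int, Sequence[MotionWindow]], m: int
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Assemble the per-exercise motion and one-hot target cell matrices.

    Returns six 800 x m motion cells (exercise 1..6 in order) and six 6 x m
    target cells whose k-th row is all ones for exercise k.  The first *m*
    windows of each exercise are used, in input order.
    """
    M: list[np.ndarray] = []
    T: list[np.ndarray] = []
    for k in range(1, N_EXERCISES + 1):
        wins = windows_by_exercise.get(k, [])
        if len(wins) < m:
            raise ShortageError(f"exercise {k} supplies {len(wins)} windows, need {m}")
        cell = np.column_stack([w.values for w in wins[:m]])
        target = np.zeros((N_EXERCISES, m))
        target[k - 1, :] = 1.0
        M.append(cell)
        T.append(target)
    return M, T


def stack_cells(cells: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate per-exercise cells column-wise.

    Returns the stacked matrix and a 1-based label per column.
    """
    labels = np.concatenate(
        [np.full(cell.shape[1], k, dtype=int) for k, cell in enumerate(cells, start=1)]
    )
    return np.concatenate(cells, axis=1), labels


class FeatureScaler:
    """Per-feature-block min-max scaling of 800-vectors into [-1, 1].

    Fitted on training columns only and stored with the model so that
    recognition applies the identical mapping.  A constant feature maps
    to 0.
    """

    def __init__(self, lo: np.ndarray | None = None, hi: np.ndarray | None = None):
        self.lo = lo  # (4,)
        self.hi = hi

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        if X.shape[0] != INPUT_LENGTH:
            raise ValueError(f"expected {INPUT_LENGTH} rows")
        blocks = X.reshape(N_FEATURES, WINDOW_TICKS, -1)
        self.lo = blocks.min(axis=(1, 2))
        self.hi = blocks.max(axis=(1, 2))
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.lo is None:
            raise ValueError("scaler not fitted")
        one_d = X.ndim == 1
        X = X.reshape(INPUT_LENGTH, -1)
        lo = np.repeat(self.lo, WINDOW_TICKS)[:, None]
        hi = np.repeat(self.hi, WINDOW_TICKS)[:, None]
        span = hi - lo
        span = np.where(span == 0, 1.0, span)
        out = 2.0 * (X - lo) / span - 1.0
        out = np.where((hi - lo) == 0, 0.0, out)
        return out[:, 0] if one_d else out

    def to_dict(self) -> dict:
        return {"lo": self.lo.tolist(), "hi": self.hi.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        return cls(lo=np.asarray(d["lo"], dtype=float), hi=np.asarray(d["hi"], dtype=float))
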