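"""Frequency-domain feature pipeline.

Signals from cyclical exercises are transformed to one-sided amplitude
spectra; peaks are grouped into a primary peak and the secondary peaks
exceeding a quarter of its amplitude.  For robust feature selection the
signal is low-pass filtered (20-tap FIR) and downsampled 1-in-5, the
spectrum is enveloped on a frequency grid, and the squared-magnitude
difference between envelope and original drives the choice of the grid
parameters (omega1, delta_omega).

Spectrum magnitudes use the one-sided amplitude convention 2|X_k|/N with
the DC and Nyquist bins unhalved (|X_k|/N), so a unit-amplitude tone at an
exact bin reads 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import firwin

MIN_SIGNAL_LEN = 16

__all__ = [
    "SpectrumHistogram",
    "PeakGroups",
    "FilterParams",
    "NoPeakError",
    "spectrum",
    "peak_groups",
    "lowpass_downsample",
    "envelope_spectrum",
    "magnitude_difference",
    "select_filter_params",
]


class NoPeakError(ValueError):
    """Spectrum has no nonzero content to take peaks from."""


@dataclass(frozen=True)
class SpectrumHistogram:
    """One-sided magnitude spectrum of a uniformly sampled signal."""

    frequencies: np.ndarray  # Hz, ascending from 0
    magnitudes: np.ndarray  # amplitude units, nonnegative
    rate: float  # Hz
    channel: str = ""

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        m = np.asarray(self.magnitudes, dtype=float)
        if f.shape != m.shape or f.ndim != 1:
            raise ValueError("frequencies and magnitudes must be matching 1-D arrays")
        if (f < 0).any() or (np.diff(f) <= 0).any():
            raise ValueError("frequencies must be nonnegative and ascending")
        if (m < 0).any():
            raise ValueError("magnitudes must be nonnegative")

    @property
    def resolution(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    @property
    def nyquist(self) -> float:
        return self.rate / 2.0


@dataclass(frozen=True)
class PeakGroups:
    """Primary spectral peak and the secondaries above a quarter of it."""

    primary: tuple[float, float]  # (frequency, magnitude)
    secondaries: tuple[tuple[float, float], ...]

    def __post_init__(self):
        thr = self.primary[1] / 4.0
        if any(mag <= thr for _, mag in self.secondaries):
            raise ValueError("every secondary must exceed a quarter of the primary")


@dataclass(frozen=True)
class FilterParams:
    """Low-pass/downsampling and envelope-grid parameters.

    ``omega1`` is the cutoff (and envelope-grid anchor) normalized to the
    Nyquist frequency; ``delta_omega`` the grid increment in the same
    normalized units.
    """

    omega1: float = 0.115
    delta_omega: float = 0.1
    order: int = 20
    factor: int = 5
    delta_e: float | None = None

    def __post_init__(self):
        if not 0 < self.omega1 < 1:
            raise ValueError("omega1 must lie in (0, 1)")
        if self.delta_omega <= 0:
            raise ValueError("delta_omega must be positive")
        if self.order < 1 or self.factor < 1:
            raise ValueError("order and factor must be >= 1")


def spectrum(signal, rate: float, channel: str = "") -> SpectrumHistogram:
    """One-sided amplitude spectrum (see module docstring for scaling)."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or len(x) < MIN_SIGNAL_LEN:
        raise ValueError(f"need a 1-D signal of at least {MIN_SIGNAL_LEN} samples")
    n = len(x)
    X = np.fft.rfft(x)
    mags = 2.0 * np.abs(X) / n
    mags[0] /= 2.0
    if n % 2 == 0:
        mags[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    return SpectrumHistogram(frequencies=freqs, magnitudes=mags, rate=rate, channel=channel)


def peak_groups(spec: SpectrumHistogram) -> PeakGroups:
    """Primary peak plus secondary peaks above a quarter of its amplitude.

    The primary is the global maximum excluding DC.  Secondary candidates
    are local maxima over the quarter threshold; candidates within one
    resolution step of a taller candidate (or of the primary) merge into
    that group.
    """
    mags = np.asarray(spec.magnitudes, dtype=float)
    freqs = np.asarray(spec.frequencies, dtype=float)
    if len(mags) < 2 or not (mags[1:] > 0).any():
        raise NoPeakError("spectrum has no nonzero non-DC content")
    body = mags.copy()
    body[0] = -np.inf  # DC excluded from the peak search
    p_idx = int(body.argmax())
    p_mag = mags[p_idx]
    thr = p_mag / 4.0

    # local maxima (plateau-tolerant on the left, strict on the right)
    cand = [
        i
        for i in range(1, len(mags))
        if mags[i] > thr
        and mags[i] >= mags[i - 1]
        and (i == len(mags) - 1 or mags[i] > mags[i + 1])
    ]
    # merge candidates within one resolution bin of a taller one
    cand.sort(key=lambda i: (-mags[i], i))
    kept: list[int] = [p_idx]
    for i in cand:
        if all(abs(i - j) > 1 for j in kept):
            kept.append(i)
    secondaries = tuple(
        (float(freqs[i]), float(mags[i])) for i in sorted(kept[1:])
    )
    return PeakGroups(primary=(float(freqs[p_idx]), float(p_mag)), secondaries=secondaries)


def lowpass_downsample(signal, params: FilterParams = FilterParams()) -> np.ndarray:
    """FIR low-pass (windowed-sinc, cutoff ``omega1`` x Nyquist) then 1-in-5.

    The input is edge-padded so the filter is warmed up, and the output is
    shifted by the group delay (order/2 samples); the result holds
    ``floor((N - delay) / factor)`` samples.
    """
    x = np.asarray(signal, dtype=float)
    n = len(x)
    if n <= params.order * params.factor:
        raise ValueError(f"signal too short for order {params.order} x factor {params.factor}")
    taps = firwin(params.order + 1, params.omega1)
    delay = params.order // 2
    padded = np.concatenate([np.full(params.order, x[0]), x])
    y = np.convolve(padded, taps, mode="full")[params.order + delay :]
    n_out = (n - delay) // params.factor
    return y[: n_out * params.factor : params.factor]


def envelope_spectrum(
    spec: SpectrumHistogram, omega1: float, delta_omega: float
) -> SpectrumHistogram:
    """Upper envelope built from peak bins on the normalized frequency grid.

    Grid cells of width ``delta_omega`` (normalized to Nyquist) are anchored
    at ``omega1``; the tallest bin of each cell becomes a knot, the knots are
    joined by linear interpolation, and the result is raised to the original
    wherever it would dip below it, so the envelope dominates pointwise.
    """
    if not 0 < omega1 < 1 or delta_omega <= 0:
        raise ValueError("invalid envelope grid parameters")
    if delta_omega * spec.nyquist < spec.resolution:
        raise ValueError("delta_omega is below the spectrum's frequency resolution")
    freqs = np.asarray(spec.frequencies, dtype=float)
    mags = np.asarray(spec.magnitudes, dtype=float)
    norm = freqs / spec.nyquist

    # cell k covers [omega1 + (k - 1/2) dw, omega1 + (k + 1/2) dw)
    cell = np.round((norm - omega1) / delta_omega).astype(int)
    knot_f: list[float] = [freqs[0]]
    knot_m: list[float] = [mags[0]]
    for c in np.unique(cell):
        members = np.flatnonzero(cell == c)
        top = members[mags[members].argmax()]
        if freqs[top] > knot_f[-1]:
            knot_f.append(freqs[top])
            knot_m.append(mags[top])
    if freqs[-1] > knot_f[-1]:
        knot_f.append(freqs[-1])
        knot_m.append(mags[-1])

    env = np.interp(freqs, knot_f, knot_m)
    env = np.maximum(env, mags)
    return replace(spec, magnitudes=env)


def magnitude_difference(enveloped: SpectrumHistogram, original: SpectrumHistogram) -> float:
    """Difference of summed squared magnitudes, envelope minus original."""
    if not np.array_equal(enveloped.frequencies, original.frequencies):
        raise ValueError("spectra must share one bin grid")
    return float(
        np.sum(np.asarray(enveloped.magnitudes) ** 2)
        - np.sum(np.asarray(original.magnitudes) ** 2)
    )


def select_filter_params(
    spectra: Sequence[SpectrumHistogram],
    omega1_grid: Sequence[float],
    delta_omega_grid: Sequence[float],
) -> tuple[FilterParams, np.ndarray]:
    """Pick the modal per-spectrum minimal-difference grid pair.

    For every spectrum the squared-magnitude difference is evaluated on each
    (omega1, delta_omega) pair; each spectrum votes for its minimal pair and
    the pair with the most votes wins, ties broken toward smaller
    delta_omega then smaller omega1.  Returns the winning parameters (with
    the mean winning difference) and the full difference table of shape
    (n_spectra, len(omega1_grid), len(delta_omega_grid)).
    """
    omega1_grid = list(omega1_grid)
    delta_omega_grid = list(delta_omega_grid)
    if not spectra or not omega1_grid or not delta_omega_grid:
        raise ValueError("spectra and parameter grids must be nonempty")
    table = np.empty((len(spectra), len(omega1_grid), len(delta_omega_grid)))
    for s, spec in enumerate(spectra):
        for i, w1 in enumerate(omega1_grid):
            for j, dw in enumerate(delta_omega_grid):
                table[s, i, j] = magnitude_difference(envelope_spectrum(spec, w1, dw), spec)

    votes: dict[tuple[int, int], int] = {}
    for s in range(len(spectra)):
        flat = table[s]
        best = np.inf
        best_ij = (0, 0)
        # scan ordered so ties prefer smaller delta_omega, then smaller omega1
        for j in range(len(delta_omega_grid)):
            for i in range(len(omega1_grid)):
                if flat[i, j] < best - 1e-15:
                    best = flat[i, j]
                    best_ij = (i, j)
        votes[best_ij] = votes.get(best_ij, 0) + 1

    win_ij = min(votes, key=lambda ij: (-votes[ij], delta_omega_grid[ij[1]], omega1_grid[ij[0]]))
    i, j = win_ij
    winners = [table[s, i, j] for s in range(len(spectra))]
    params = FilterParams(
        omega1=omega1_grid[i], delta_omega=delta_omega_grid[j], delta_e=float(np.mean(winners))
    )
    return params, table
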