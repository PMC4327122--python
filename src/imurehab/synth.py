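"""Synthetic six-exercise IMU signal simulator.

No recordings exist for the original experiments, so this generator stands
in for the wearable hardware.  Each exercise template pins the documented
signal signature — the waveform family and peak included angle of its
tilt-angle trace, and the per-axis spectral peak groups — and the generator
builds a gravity-direction stream whose consecutive-sample included angles
trace that family waveform while the z-axis carries the template's tones.

Construction: the unit gravity direction holds a fixed vertical component
(``tilt``) and rotates in the horizontal plane along a bounded periodic
phase path phi(t); the planar peak swing is solved from the spherical
geometry so the 3-D included angle peaks at the template angle.  Small
additive tones on every axis carry the template frequencies, and seeded
Gaussian noise is added last.  The same templates feed an ADC packet
encoder (with an optional corruption model) so the packet pipeline can be
tested against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .features import RATE_HZ, STRIDE_TICKS, WINDOW_TICKS, angle_series
from .packet_io import (
    BLOCK_SIZE,
    DEFAULT_ADC_BITS,
    CalibratedSample,
    ChannelCalibration,
    SensorPacket,
    default_calibrations,
    samples_to_array,
)

FAMILIES = ("gentle", "nodal", "impulse")
NYQUIST_HZ = RATE_HZ / 2.0

__all__ = [
    "FAMILIES",
    "ExerciseTemplate",
    "default_templates",
    "simulate_exercise",
    "duration_for_windows",
    "encode_session",
]


@dataclass(frozen=True)
class ExerciseTemplate:
    """Signal signature of one exercise.

    ``fundamentals``/``secondary_freqs``/``secondary_ratios`` give the
    per-axis (x, y, z) tone frequencies in Hz and the secondary-to-primary
    amplitude ratios; ``extra_tones`` lists additional (axis, Hz, ratio)
    minor components.  ``tilt`` is the resting vertical component of the
    unit gravity direction.
    """

    exercise_id: int
    family: str
    peak_angle_deg: float
    fundamentals: tuple[float, float, float]
    secondary_freqs: tuple[float, float, float] = (0.0, 0.0, 0.0)
    secondary_ratios: tuple[float, float, float] = (0.0, 0.0, 0.0)
    extra_tones: tuple[tuple[str, float, float], ...] = ()
    tilt: float = 0.4
    tone_amp_z: float = 0.08
    tone_amp_xy: float = 0.05
    noise_sd: float = 0.02
    duration_s: float = 60.0

    def __post_init__(self):
        if not 1 <= self.exercise_id <= 6:
            raise ValueError("exercise_id must be 1..6")
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if not 0.0 < self.peak_angle_deg <= 180.0:
            raise ValueError("peak angle must lie in (0, 180]")
        freqs = list(self.fundamentals) + list(self.secondary_freqs) + [f for _, f, _ in self.extra_tones]
        if any(f >= NYQUIST_HZ for f in freqs):
            raise ValueError(f"all tone frequencies must stay below Nyquist ({NYQUIST_HZ} Hz)")
        if not 0.0 <= self.tilt < 1.0:
            raise ValueError("tilt must lie in [0, 1)")


def default_templates() -> list[ExerciseTemplate]:
    """The six built-in exercise templates.

    Peak included angles: gentle 80 and 20 degrees (Ex.1, Ex.2), nodal 80
    and 40 degrees (Ex.3, Ex.5), impulse 20 and 160 degrees (Ex.4, Ex.6).
    Ex.3 carries per-axis primary tones at (0.2, 0.25, 0.25) Hz with
    secondaries at (0.4, 0.55, 0.55) Hz and a minor extra component at
    0.8 Hz on a_y.
    """
    return [
        ExerciseTemplate(1, "gentle", 80.0, (0.5, 0.5, 0.5), tilt=0.35),
        ExerciseTemplate(2, "gentle", 20.0, (0.4, 0.4, 0.4), tilt=0.55),
        ExerciseTemplate(
            3,
            "nodal",
            80.0,
            (0.2, 0.25, 0.25),
            secondary_freqs=(0.4, 0.55, 0.55),
            secondary_ratios=(0.3, 0.3, 0.3),
            extra_tones=(("ay", 0.8, 0.26),),
            tilt=0.15,
        ),
        ExerciseTemplate(4, "impulse", 20.0, (0.5, 0.5, 0.5), tilt=0.7),
        ExerciseTemplate(5, "nodal", 40.0, (0.32, 0.32, 0.32), tilt=0.45),
        ExerciseTemplate(6, "impulse", 160.0, (0.4, 0.4, 0.4), tilt=0.1),
    ]


def duration_for_windows(n_windows: int) -> float:
    """Seconds of stream needed for exactly *n_windows* overlapped windows."""
    if n_windows < 1:
        raise ValueError("need at least one window")
    return (WINDOW_TICKS + (n_windows - 1) * STRIDE_TICKS) / RATE_HZ


def _planar_peak(peak_deg: float, tilt: float) -> float:
    """Horizontal-plane swing (rad) so the 3-D included angle peaks at *peak_deg*.

    For unit directions sharing the vertical component ``tilt`` and planar
    magnitude ``A``:  cos(theta) = A^2 cos(delta) + tilt^2, solved for the
    planar rotation delta; clamped when the requested angle is unreachable
    at this tilt.
    """
    a2 = 1.0 - tilt * tilt
    c = (math.cos(math.radians(peak_deg)) - tilt * tilt) / a2
    return math.acos(max(-1.0, min(1.0, c)))


def _phase_path(template: ExerciseTemplate, n: int) -> np.ndarray:
    """Bounded periodic horizontal phase phi(t) in radians for n ticks."""
    t = np.arange(n) / RATE_HZ
    f = template.fundamentals[2]  # the included-angle waveform follows the z fundamental
    peak_planar = _planar_peak(template.peak_angle_deg, template.tilt)
    center = 0.5 * template.exercise_id  # distinct planar rest direction per exercise
    step = 2.0 * math.sin(math.pi * f / RATE_HZ)  # peak per-tick swing of sin(2 pi f t)

    if template.family == "gentle":
        amp = peak_planar / step
        return center + amp * np.sin(2 * np.pi * f * t)
    if template.family == "nodal":
        # alternate full- and half-amplitude fundamental periods; the switch
        # falls on the sine's zero crossings so the phase stays continuous
        amp = peak_planar / step
        env = np.where(np.floor(f * t).astype(int) % 2 == 0, 1.0, 0.5)
        return center + amp * env * np.sin(2 * np.pi * f * t)
    # impulse: small jitter plus two opposite phase jumps per period
    period = int(round(RATE_HZ / f))
    jitter_amp = 0.05 * peak_planar / step
    phi = center + jitter_amp * np.sin(2 * np.pi * f * t)
    ticks = np.arange(n)
    phase = ticks % period
    jump = np.zeros(n)
    jump[phase >= 1] += peak_planar
    jump[phase >= 1 + period // 2] -= peak_planar
    return phi + jump


def _tones(template: ExerciseTemplate, n: int) -> dict[str, np.ndarray]:
    t = np.arange(n) / RATE_HZ
    out = {}
    for axis, name in enumerate(("ax", "ay", "az")):
        amp = template.tone_amp_z if name == "az" else template.tone_amp_xy
        sig = np.sin(2 * np.pi * template.fundamentals[axis] * t)
        if template.secondary_ratios[axis] > 0:
            sig = sig + template.secondary_ratios[axis] * np.sin(
                2 * np.pi * template.secondary_freqs[axis] * t
            )
        out[name] = amp * sig
    for axis_name, freq, ratio in template.extra_tones:
        amp = template.tone_amp_z if axis_name == "az" else template.tone_amp_xy
        out[axis_name] = out[axis_name] + amp * ratio * np.sin(2 * np.pi * freq * t)
    return out


def simulate_exercise(
    template: ExerciseTemplate,
    seed: int = 0,
    duration_s: float | None = None,
    node_id: int = 2,
) -> tuple[list[CalibratedSample], dict]:
    """Generate a calibrated sample stream plus its ground-truth record.

    The stream runs at 8 samples/s for ``duration_s`` seconds (template
    default 60).  The ground truth holds the per-tick ideal included angle
    (computed on the noiseless stream), the phase path, and the template
    parameters, so downstream stages can be checked against construction.
    """
    duration = template.duration_s if duration_s is None else duration_s
    n = int(round(duration * RATE_HZ))
    rng = np.random.default_rng(seed)
    t = np.arange(n) / RATE_HZ

    phi = _phase_path(template, n)
    planar = math.sqrt(max(1.0 - template.tilt**2, 1e-12))
    tones = _tones(template, n)
    clean = np.column_stack(
        [
            planar * np.cos(phi) + tones["ax"],
            planar * np.sin(phi) + tones["ay"],
            template.tilt + tones["az"],
        ]
    )
    ideal_theta = angle_series(clean)

    acc = clean + rng.normal(0.0, template.noise_sd, size=clean.shape)

    # angular velocity: horizontal-phase rate on z, small tones elsewhere
    dphi = np.gradient(np.degrees(phi)) * RATE_HZ
    gyro = np.column_stack(
        [
            40.0 * np.sin(2 * np.pi * template.fundamentals[0] * t),
            40.0 * np.cos(2 * np.pi * template.fundamentals[1] * t),
            np.clip(dphi, -450.0, 450.0),
        ]
    )
    gyro = gyro + rng.normal(0.0, 5.0, size=gyro.shape)
    gyro = np.clip(gyro, -495.0, 495.0)

    samples = [
        CalibratedSample(t=float(tk), a=acc[i], w=gyro[i], node_id=node_id)
        for i, tk in enumerate(t)
    ]
    ground_truth = {
        "template": asdict(template),
        "seed": seed,
        "n_samples": n,
        "ideal_theta_deg": ideal_theta.tolist(),
        "phase_rad": phi.tolist(),
    }
    return samples, ground_truth


@dataclass
class CorruptionRates:
    """Per-packet probabilities of each corruption kind (mutually exclusive)."""

    truncate: float = 0.0
    out_of_range: float = 0.0
    duplicate_seq: float = 0.0

    def __post_init__(self):
        if min(self.truncate, self.out_of_range, self.duplicate_seq) < 0:
            raise ValueError("corruption rates must be nonnegative")
        if self.truncate + self.out_of_range + self.duplicate_seq > 1:
            raise ValueError("corruption rates must sum to at most 1")


def encode_session(
    samples: list[CalibratedSample],
    calibrations: list[ChannelCalibration] | None = None,
    bits: int = DEFAULT_ADC_BITS,
    count_sd: float = 2.0,
    corruption: CorruptionRates | None = None,
    seed: int = 0,
) -> tuple[list[SensorPacket], list[dict]]:
    """Encode a sample stream as ADC packets, optionally corrupting some.

    Each sample becomes one packet whose channel blocks hold 128 rounded
    Gaussian counts (sd ``count_sd``) centered on the inverse-calibrated
    true value.  Corruption (chosen per packet by seeded draw) truncates a
    block, pushes a count out of range, or duplicates the previous packet's
    seq; the returned manifest records ``{"index", "seq", "kind"}`` for
    every corrupted packet.
    """
    if calibrations is None:
        calibrations = default_calibrations(bits=bits)
    corruption = corruption or CorruptionRates()
    rng = np.random.default_rng(seed)
    hi = (1 << bits) - 1

    packets: list[SensorPacket] = []
    manifest: list[dict] = []
    for i, s in enumerate(samples):
        values = list(s.a) + list(s.w)
        blocks = []
        for v, cal in zip(values, calibrations):
            mu = (v + cal.baseline) / cal.scale + cal.offset
            counts = np.clip(np.round(rng.normal(mu, count_sd, BLOCK_SIZE)), 0, hi)
            blocks.append(counts.astype(np.int64))
        seq = i
        r = rng.random()
        kind = None
        if r < corruption.truncate:
            kind = "incomplete"
            ch = int(rng.integers(0, len(blocks)))
            blocks[ch] = blocks[ch][:-1]
        elif r < corruption.truncate + corruption.out_of_range:
            kind = "out_of_range"
            ch = int(rng.integers(0, len(blocks)))
            j = int(rng.integers(0, len(blocks[ch])))
            blocks[ch] = blocks[ch].copy()
            blocks[ch][j] = hi + 1 + int(rng.integers(0, 8))
        elif r < corruption.truncate + corruption.out_of_range + corruption.duplicate_seq and i > 0:
            kind = "duplicate_seq"
            seq = packets[-1].seq
        if kind is not None:
            manifest.append({"index": i, "seq": int(seq), "kind": kind})
        packets.append(SensorPacket(node_id=s.node_id, seq=seq, t=s.t, channels=tuple(blocks)))
    return packets, manifest
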