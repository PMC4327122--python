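"""Sensor-packet parsing, validation, ADC conversion and calibration.

A wearable node streams six-channel packets (tri-axial acceleration and
tri-axial angular velocity).  Each channel of a packet carries a block of
128 raw ADC counts sampled around the true analog value; the block mean is
the digital estimate of that value.  This module turns packet logs into
streams of physical-unit samples.

Packet log dialects
-------------------
``csv``
    One row per packet: ``node_id, seq, t`` followed by six channel blocks,
    each written as its length then that many counts.  The explicit length
    prefix lets incomplete (corrupted) blocks round-trip for testing the
    filtering stage.
``binary``
    Little-endian records: ``uint8 node_id, uint32 seq, float64 t``, then
    per channel ``uint16 n`` followed by ``n`` ``uint16`` counts.
"""

from __future__ import annotations

import csv as _csv
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

#: channels in payload order
CHANNEL_NAMES = ("ax", "ay", "az", "wx", "wy", "wz")
N_CHANNELS = 6
BLOCK_SIZE = 128
DEFAULT_ADC_BITS = 10

__all__ = [
    "CHANNEL_NAMES",
    "N_CHANNELS",
    "BLOCK_SIZE",
    "DEFAULT_ADC_BITS",
    "SensorPacket",
    "ChannelCalibration",
    "CalibratedSample",
    "PacketParseError",
    "OrderingError",
    "RejectionReport",
    "parse_packet_log",
    "write_packet_log",
    "filter_packets",
    "adc_to_value",
    "packets_to_samples",
    "samples_to_array",
    "write_samples_csv",
    "read_samples_csv",
    "default_calibrations",
    "save_calibrations",
    "load_calibrations",
]


class PacketParseError(ValueError):
    """Malformed packet record; carries the 1-based line/record number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class OrderingError(ValueError):
    """Timestamps not strictly increasing."""


@dataclass(frozen=True)
class SensorPacket:
    """One node's time-stamped six-channel ADC payload.

    ``channels`` is a tuple of six integer arrays, one per channel in the
    order of :data:`CHANNEL_NAMES`.  Blocks are normally 128 counts long but
    may be shorter for corrupted packets; validation is the job of
    :func:`filter_packets`, not the constructor.
    """

    node_id: int
    seq: int
    t: float
    channels: tuple[np.ndarray, ...]

    def is_complete(self) -> bool:
        return len(self.channels) == N_CHANNELS and all(
            len(b) == BLOCK_SIZE for b in self.channels
        )

    def in_range(self, bits: int = DEFAULT_ADC_BITS) -> bool:
        hi = (1 << bits) - 1
        return all(
            (np.asarray(b) >= 0).all() and (np.asarray(b) <= hi).all()
            for b in self.channels
        )


@dataclass(frozen=True)
class ChannelCalibration:
    """Linear ADC-count to physical-unit mapping for one channel.

    value = (mean(counts) - offset) * scale - baseline
    """

    offset: float
    scale: float
    baseline: float = 0.0

    def __post_init__(self):
        if self.scale == 0:
            raise ValueError("calibration scale must be nonzero")


@dataclass(frozen=True)
class CalibratedSample:
    """Physical-unit reading at one tick: acceleration in g, rate in deg/s."""

    t: float
    a: np.ndarray  # (3,) in g
    w: np.ndarray  # (3,) in deg/s
    node_id: int = 2

    def __post_init__(self):
        if not (np.isfinite(self.a).all() and np.isfinite(self.w).all()):
            raise ValueError("sample components must be finite")


@dataclass
class RejectionReport:
    """Counts of rejected packets by reason plus the per-packet detail."""

    incomplete: int = 0
    out_of_range: int = 0
    duplicate_seq: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (seq, reason)

    @property
    def total(self) -> int:
        return self.incomplete + self.out_of_range + self.duplicate_seq

    def as_dict(self) -> dict:
        return {
            "incomplete": self.incomplete,
            "out_of_range": self.out_of_range,
            "duplicate_seq": self.duplicate_seq,
            "total": self.total,
        }


# ---------------------------------------------------------------------------
# log I/O


def write_packet_log(packets: Iterable[SensorPacket], path, dialect: str = "csv") -> None:
    """Write packets to *path* in the given dialect (see module docstring)."""
    path = Path(path)
    if dialect == "csv":
        with path.open("w", newline="") as fh:
            w = _csv.writer(fh)
            for p in packets:
                row: list = [p.node_id, p.seq, repr(float(p.t))]
                for block in p.channels:
                    row.append(len(block))
                    row.extend(int(c) for c in block)
                w.writerow(row)
    elif dialect == "binary":
        with path.open("wb") as fh:
            for p in packets:
                fh.write(struct.pack("<BId", p.node_id, p.seq, float(p.t)))
                for block in p.channels:
                    fh.write(struct.pack("<H", len(block)))
                    fh.write(np.asarray(block, dtype="<u2").tobytes())
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def parse_packet_log(path, dialect: str = "csv") -> list[SensorPacket]:
    """Parse a packet log into packets in file order.

    Raises :class:`PacketParseError` (naming the offending line/record) on a
    structurally malformed record; never repairs silently.
    """
    path = Path(path)
    if dialect == "csv":
        return _parse_csv(path)
    if dialect == "binary":
        return _parse_binary(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _parse_csv(path: Path) -> list[SensorPacket]:
    packets: list[SensorPacket] = []
    with path.open(newline="") as fh:
        for lineno, row in enumerate(_csv.reader(fh), start=1):
            if not row:
                continue
            if len(row) < 3 + N_CHANNELS:
                raise PacketParseError("too few fields for a packet header", lineno)
            try:
                node_id, seq, t = int(row[0]), int(row[1]), float(row[2])
            except ValueError as exc:
                raise PacketParseError(f"bad header field: {exc}", lineno) from None
            pos = 3
            blocks = []
            for ch in range(N_CHANNELS):
                if pos >= len(row):
                    raise PacketParseError(f"missing block {ch}", lineno)
                try:
                    n = int(row[pos])
                except ValueError:
                    raise PacketParseError(f"bad block length at field {pos}", lineno) from None
                pos += 1
                if pos + n > len(row):
                    raise PacketParseError(
                        f"truncated record: block {ch} promises {n} counts", lineno
                    )
                try:
                    counts = np.array([int(v) for v in row[pos : pos + n]], dtype=np.int64)
                except ValueError:
                    raise PacketParseError(f"non-integer count in block {ch}", lineno) from None
                blocks.append(counts)
                pos += n
            if pos != len(row):
                raise PacketParseError(f"{len(row) - pos} trailing fields", lineno)
            packets.append(SensorPacket(node_id, seq, t, tuple(blocks)))
    return packets


def _parse_binary(path: Path) -> list[SensorPacket]:
    data = path.read_bytes()
    packets: list[SensorPacket] = []
    pos = 0
    recno = 0
    while pos < len(data):
        recno += 1
        if pos + 13 > len(data):
            raise PacketParseError("truncated record header", recno)
        node_id, seq, t = struct.unpack_from("<BId", data, pos)
        pos += 13
        blocks = []
        for ch in range(N_CHANNELS):
            if pos + 2 > len(data):
                raise PacketParseError(f"truncated length of block {ch}", recno)
            (n,) = struct.unpack_from("<H", data, pos)
            pos += 2
            if pos + 2 * n > len(data):
                raise PacketParseError(f"truncated block {ch}", recno)
            blocks.append(np.frombuffer(data, dtype="<u2", count=n, offset=pos).astype(np.int64))
            pos += 2 * n
        packets.append(SensorPacket(node_id, seq, t, tuple(blocks)))
    return packets


# ---------------------------------------------------------------------------
# validation / conversion


def filter_packets(
    packets: Sequence[SensorPacket], bits: int = DEFAULT_ADC_BITS
) -> tuple[list[SensorPacket], RejectionReport]:
    """Drop invalid packets, reporting rejections by reason.

    A packet is rejected iff a channel block is incomplete, a count is
    outside the ADC range for *bits*, or its ``seq`` repeats one already
    seen (first occurrence kept).  Never raises on bad data.
    """
    report = RejectionReport()
    seen: set[int] = set()
    valid: list[SensorPacket] = []
    for p in packets:
        if not p.is_complete():
            report.incomplete += 1
            report.rejected.append((p.seq, "incomplete"))
            continue
        if not p.in_range(bits):
            report.out_of_range += 1
            report.rejected.append((p.seq, "out_of_range"))
            continue
        if p.seq in seen:
            report.duplicate_seq += 1
            report.rejected.append((p.seq, "duplicate_seq"))
            continue
        seen.add(p.seq)
        valid.append(p)
    return valid, report


def adc_to_value(block: np.ndarray, cal: ChannelCalibration) -> float:
    """Convert one complete 128-count ADC block to a physical value.

    The digital estimate is the arithmetic mean of the counts (the mean of
    the empirical count distribution), mapped linearly and baseline
    corrected: ``(mean - offset) * scale - baseline``.
    """
    block = np.asarray(block)
    if len(block) != BLOCK_SIZE:
        raise ValueError(f"block must hold exactly {BLOCK_SIZE} counts, got {len(block)}")
    return (float(block.mean()) - cal.offset) * cal.scale - cal.baseline


def packets_to_samples(
    packets: Sequence[SensorPacket], calibrations: Sequence[ChannelCalibration]
) -> list[CalibratedSample]:
    """Convert filtered packets into one calibrated sample each.

    Expects already-filtered packets (complete blocks) and one calibration
    per channel in payload order.  Raises :class:`OrderingError` if the
    timestamps are not strictly increasing.
    """
    if len(calibrations) != N_CHANNELS:
        raise ValueError(f"need {N_CHANNELS} channel calibrations")
    samples: list[CalibratedSample] = []
    prev_t = -np.inf
    for p in packets:
        if p.t <= prev_t:
            raise OrderingError(f"timestamp {p.t} not after {prev_t} (seq {p.seq})")
        prev_t = p.t
        vals = [adc_to_value(b, c) for b, c in zip(p.channels, calibrations)]
        samples.append(
            CalibratedSample(t=p.t, a=np.array(vals[:3]), w=np.array(vals[3:]), node_id=p.node_id)
        )
    return samples


def samples_to_array(samples: Sequence[CalibratedSample]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (t, acc, gyro) arrays of shapes (n,), (n,3), (n,3)."""
    t = np.array([s.t for s in samples])
    a = np.stack([s.a for s in samples]) if samples else np.empty((0, 3))
    w = np.stack([s.w for s in samples]) if samples else np.empty((0, 3))
    return t, a, w


def write_samples_csv(samples: Sequence[CalibratedSample], path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(("t",) + CHANNEL_NAMES)
        for s in samples:
            w.writerow([repr(float(s.t))] + [repr(float(v)) for v in s.a] + [repr(float(v)) for v in s.w])


def read_samples_csv(path, node_id: int = 2) -> list[CalibratedSample]:
    out = []
    with Path(path).open(newline="") as fh:
        rd = _csv.reader(fh)
        header = next(rd)
        if tuple(header) != ("t",) + CHANNEL_NAMES:
            raise ValueError(f"unexpected sample CSV header: {header}")
        for row in rd:
            vals = [float(v) for v in row]
            out.append(
                CalibratedSample(t=vals[0], a=np.array(vals[1:4]), w=np.array(vals[4:7]), node_id=node_id)
            )
    return out


# ---------------------------------------------------------------------------
# calibration defaults / config file


def default_calibrations(
    bits: int = DEFAULT_ADC_BITS,
    accel_range_g: float = 2.0,
    gyro_range_dps: float = 500.0,
) -> list[ChannelCalibration]:
    """Symmetric full-scale calibrations: mid-scale offset, ±range mapping.

    Acceleration channels span ±*accel_range_g* g, angular-velocity channels
    ±*gyro_range_dps* deg/s, over the full ADC code range.
    """
    levels = 1 << bits
    offset = (levels - 1) / 2.0
    a_scale = 2.0 * accel_range_g / levels
    w_scale = 2.0 * gyro_range_dps / levels
    return [ChannelCalibration(offset, a_scale) for _ in range(3)] + [
        ChannelCalibration(offset, w_scale) for _ in range(3)
    ]


def save_calibrations(calibrations: Sequence[ChannelCalibration], path) -> None:
    doc = {
        name: {"offset": c.offset, "scale": c.scale, "baseline": c.baseline}
        for name, c in zip(CHANNEL_NAMES, calibrations)
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_calibrations(path) -> list[ChannelCalibration]:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        return [
            ChannelCalibration(
                offset=float(doc[name]["offset"]),
                scale=float(doc[name]["scale"]),
                baseline=float(doc[name].get("baseline", 0.0)),
            )
            for name in CHANNEL_NAMES
        ]
    except KeyError as exc:
        raise ValueError(f"calibration file missing section {exc}") from None
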