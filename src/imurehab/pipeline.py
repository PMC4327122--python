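"""End-to-end experiment orchestration shared by the CLI, tests and the
acceptance report: simulate -> encode -> filter -> calibrate -> window ->
train -> recognize -> score."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bpnn import NetworkModel, TrainingConfig, train
from .features import MotionWindow, build_matrices, make_windows, stack_cells
from .packet_io import default_calibrations, filter_packets, packets_to_samples
from .recognition import decode, recognition_rate, recognize
from .synth import ExerciseTemplate, default_templates, duration_for_windows, encode_session, simulate_exercise

__all__ = ["ExperimentResult", "simulate_windows", "run_recognition_experiment"]


@dataclass
class ExperimentResult:
    """Held-out scoring of one trained model."""

    model: NetworkModel
    per_class: dict[int, float]
    overall: float
    n_test: int
    decoded: np.ndarray = field(repr=False, default=None)
    truth: np.ndarray = field(repr=False, default=None)


def simulate_windows(
    template: ExerciseTemplate,
    n_windows: int,
    seed: int,
    via_packets: bool = True,
) -> list[MotionWindow]:
    """Simulate exactly *n_windows* labeled windows for one exercise.

    With ``via_packets`` the stream passes through the full ADC encode /
    filter / calibrate path instead of being windowed directly.
    """
    duration = duration_for_windows(n_windows)
    samples, _ = simulate_exercise(template, seed=seed, duration_s=duration)
    if via_packets:
        packets, _ = encode_session(samples, seed=seed + 1)
        valid, _ = filter_packets(packets)
        samples = packets_to_samples(valid, default_calibrations())
    windows = make_windows(samples, label=template.exercise_id)
    if len(windows) < n_windows:
        raise RuntimeError(f"simulation produced {len(windows)} windows, wanted {n_windows}")
    return windows[:n_windows]


def run_recognition_experiment(
    seed: int,
    n_windows: int = 72,
    config: TrainingConfig | None = None,
    templates: list[ExerciseTemplate] | None = None,
    via_packets: bool = True,
) -> ExperimentResult:
    """Scaled-down replication of the recognition experiment.

    Simulates *n_windows* windows for each of the six exercises, trains one
    network with the stratified split from *config*, and scores the decoded
    labels of the held-out test columns.
    """
    if config is None:
        config = TrainingConfig(seed=seed)
    templates = templates if templates is not None else default_templates()

    windows_by_ex = {}
    for k, template in enumerate(templates, start=1):
        windows_by_ex[k] = simulate_windows(template, n_windows, seed=seed * 1000 + k, via_packets=via_packets)

    M, T = build_matrices(windows_by_ex, m=n_windows)
    model = train(M, T, config)

    X, labels = stack_cells(M)
    test_idx = np.asarray(model.split_indices["test"], dtype=int)
    decoded = decode(recognize(model, X[:, test_idx]))
    truth = labels[test_idx]
    per_class, overall = recognition_rate(decoded, truth)
    return ExperimentResult(
        model=model,
        per_class=per_class,
        overall=overall,
        n_test=len(test_idx),
        decoded=decoded,
        truth=truth,
    )
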