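import numpy as np
import pytest

from imurehab.features import INPUT_LENGTH, WINDOW_TICKS, MotionWindow
from imurehab.packet_io import default_calibrations
from imurehab.synth import default_templates, simulate_exercise


@pytest.fixture
def calibrations():
    return default_calibrations()


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def ex1_session(templates):
    """60-s Ex.1 stream plus ground truth, seeded."""
    return simulate_exercise(templates[0], seed=11)


def window_from_blocks(ax, ay, az, theta=None, label=None):
    """Build a MotionWindow from explicit 200-value feature blocks."""
    blocks = []
    for b in (ax, ay, az):
        b = np.broadcast_to(np.asarray(b, dtype=float), (WINDOW_TICKS,))
        blocks.append(b)
    theta = np.zeros(WINDOW_TICKS) if theta is None else np.broadcast_to(theta, (WINDOW_TICKS,))
    values = np.concatenate(blocks + [theta])
    assert values.shape == (INPUT_LENGTH,)
    return MotionWindow(values=values, label=label)
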