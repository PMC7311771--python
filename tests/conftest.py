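import numpy as np
import pytest

from mmspike.kinematics import SpeedSeries
from mmspike.motion_io import MotionTrace


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


@pytest.fixture
def simple_trace():
    """Five-frame trace with motion along single axes."""
    translations = np.array(
        [[0.0, 0, 0], [1, 0, 0], [3, 0, 0], [3, 4, 0], [3, 4, 4]]
    )
    rotations = np.array(
        [[0.0, 0, 0], [0, 0, 90], [0, 0, 90], [1, 2, 92], [1, 2, 92]]
    )
    return MotionTrace("s1", dt=1.0, rotations=rotations, translations=translations)


def make_speed(values, dt=1.0, kind="linear", subject_id="s"):
    return SpeedSeries(subject_id, kind, dt, np.asarray(values, dtype=float))


@pytest.fixture
def toy_speed():
    return make_speed([1, 3, 1, 5, 1])
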