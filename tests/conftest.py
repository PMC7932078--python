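import numpy as np
import pytest

from snakescomp.gaze import GazeStream
from snakescomp.stimulus import DEFAULT_GEOMETRY, build_layout


@pytest.fixture
def geometry():
    return DEFAULT_GEOMETRY


@pytest.fixture
def pair_layout():
    return build_layout("exp1_pair", +1)


def make_stream(positions, rate_hz=90.0, valid=None):
    """Build a GazeStream from (x, y) pairs at a fixed sample rate."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    t = np.arange(n) * 1000.0 / rate_hz
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return GazeStream(t, positions[:, 0], positions[:, 1], valid)
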