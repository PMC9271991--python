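import numpy as np
import pytest

from mesotrack.synthetic import ArenaGeometry
from mesotrack.trajectories import Trajectory


@pytest.fixture
def small_arena() -> ArenaGeometry:
    return ArenaGeometry(width_px=200, height_px=200)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_traj(times, xs=None, ys=None, tid="t0", ind="a", gt="bare_soil", interp=None):
    """Trajectory from a time list; positions default to (t, 0) for brevity."""
    times = np.asarray(times, dtype=int)
    if xs is None:
        xs = times.astype(float)
    if ys is None:
        ys = np.zeros(len(times))
    return Trajectory.from_points(tid, times, xs, ys, individual_id=ind, ground_type=gt,
                                  interpolated=interp)


@pytest.fixture
def traj_factory():
    return make_traj
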