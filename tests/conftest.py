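import numpy as np
import pytest

from gazefix import (
    AOIPose,
    AOITrajectory,
    GazeTrace,
    StimulusWindow,
)


def make_trace(t, points, valid=None, rate_hz=50.0):
    t = np.asarray(t, dtype=float)
    p = np.asarray(points, dtype=float)
    if p.ndim == 1:
        p = np.tile(p, (t.size, 1))
    if valid is None:
        valid = np.ones(t.size, dtype=bool)
    return GazeTrace(t=t, p=p, valid=np.asarray(valid, dtype=bool), rate_hz=rate_hz)


@pytest.fixture
def unit_pose():
    """A 2 x 1.5 rectangle in the z=0 plane, centered at the origin."""
    return AOIPose(
        t=0.0,
        center=np.zeros(3),
        axis_u=np.array([1.0, 0.0, 0.0]),
        axis_v=np.array([0.0, 1.0, 0.0]),
        half_w=2.0,
        half_h=1.5,
    )


@pytest.fixture
def static_aoi(unit_pose):
    return AOITrajectory(aoi_id="board", keyframes=(unit_pose,), kind="static")


@pytest.fixture
def window():
    return StimulusWindow(stimulus_id="s1", aoi_id="board", t_start=0.0, t_end=10.0)
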