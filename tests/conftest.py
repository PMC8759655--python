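import numpy as np
import pytest

from confinetrack.cell_sim import Track
from confinetrack.geometry import Disk


def make_track(track_id, xy, dt=10.0, radius=None, t0=0.0, frame0=0):
    """Build a Track from an (n, 2) array of positions at fixed frame interval."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    frames = np.arange(frame0, frame0 + n)
    t = t0 + (frames - frame0) * dt
    return Track(track_id, frames, t, xy[:, 0], xy[:, 1], radius=radius)


def straight_track(track_id, start, direction, step_um, n_steps, dt=10.0, **kw):
    """A constant-velocity track: ``step_um`` displacement per frame."""
    start = np.asarray(start, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    xy = start + np.outer(np.arange(n_steps + 1), d * step_um)
    return make_track(track_id, xy, dt=dt, **kw)


@pytest.fixture
def disk50():
    return Disk((0.0, 0.0), 50.0)
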