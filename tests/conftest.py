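import pytest

import placecell as pc
from placecell.maps import BinGrid


@pytest.fixture(scope="session")
def open_arena():
    return pc.open_field_arena()


@pytest.fixture(scope="session")
def track_arena():
    return pc.rectangular_track_arena()


@pytest.fixture(scope="session")
def grid(open_arena):
    return BinGrid.for_circle(open_arena, bin_size_cm=2.0)


@pytest.fixture(scope="session")
def short_trajectory(open_arena):
    """Two-minute open-field run, enough for map/statistics tests."""
    return pc.simulate_open_field_trajectory(
        open_arena, duration_s=120.0, frame_rate_hz=15.0, seed=101
    )


@pytest.fixture(scope="session")
def full_trajectory(open_arena):
    """The standard 14-min, 15-Hz open-field session."""
    return pc.simulate_open_field_trajectory(open_arena, seed=7)


@pytest.fixture(scope="session")
def track_session(track_arena):
    traj, seg = pc.simulate_track_trajectory(track_arena, n_traversals=32, seed=21)
    return traj, seg
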