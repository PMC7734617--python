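import numpy as np
import pytest

import starmaze as sm
from starmaze.maze import protocol_by_index


@pytest.fixture(scope="session")
def maze():
    return sm.build_maze()


@pytest.fixture(scope="session")
def protocol():
    return sm.default_protocol(0)


@pytest.fixture(scope="session")
def specs(protocol):
    return protocol_by_index(protocol)


@pytest.fixture(scope="session")
def training_spec(specs):
    return specs[1]  # start alley 1, reward alley 3


@pytest.fixture(scope="session")
def test_spec(specs):
    return specs[6]  # start alley 4, rewards {1, 3}


def make_trajectory(points, dt=1.0 / 120.0, rate=120.0, trial_index=None):
    """Trajectory visiting the given waypoints one sample each."""
    pts = np.asarray(points, dtype=float)
    t = np.arange(len(pts)) * dt
    return sm.Trajectory(t, pts[:, 0], pts[:, 1], rate, trial_index)


@pytest.fixture(scope="session")
def ideal_training_trajectory(maze):
    """Constant-speed sampling of the ideal alley-1 → alley-3 path."""
    from starmaze.metrics import sample_ideal_trajectory

    return sample_ideal_trajectory(sm.ideal_path(1, 3, maze), speed_m_s=8.2, rate_hz=120.0)
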