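import numpy as np
import pytest

from mpong.task_env import FrameGeometry, sample_conditions, simulate_trajectory


@pytest.fixture(scope="session")
def geom():
    return FrameGeometry()


@pytest.fixture(scope="session")
def conds200(geom):
    """The standard held-out evaluation battery: 200 unique conditions."""
    return sample_conditions(200, geom, seed=7)


@pytest.fixture(scope="session")
def conds50(geom):
    return sample_conditions(50, geom, seed=11)


@pytest.fixture(scope="session")
def trajs50(geom, conds50):
    return [simulate_trajectory(c.x0, c.y0, c.dx0, c.dy0, geom) for c in conds50]


@pytest.fixture(scope="session")
def ground_truth200(conds200):
    return np.array([c.y_final for c in conds200])
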