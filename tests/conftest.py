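import numpy as np
import pytest

from goalrec import Scenario, make_berkovitz_scenario


@pytest.fixture(scope="session")
def scenario():
    """Default two-goal scenario: 14 trajectories, 7 per goal."""
    return make_berkovitz_scenario()


@pytest.fixture(scope="session")
def triangle_scenario():
    """Small hand-checkable scenario: start at origin, goals at (+-3, 4)."""
    return Scenario(start=(0.0, 0.0), goals=[(-3.0, 4.0), (3.0, 4.0)])


@pytest.fixture()
def rng():
    return np.random.default_rng(20261001)


def random_polyline(rng, n_points, scale=10.0):
    """Random-walk polyline used as a generic geometry fixture."""
    start = rng.normal(size=2)
    steps = rng.normal(size=(n_points - 1, 2), scale=scale / n_points)
    return np.vstack([start[None, :], start + np.cumsum(steps, axis=0)])
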