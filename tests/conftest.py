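import numpy as np
import pandas as pd
import pytest

from barnspace.geometry import BarnGeometry, GridSpec
from barnspace.prep import Trajectory


@pytest.fixture(scope="session")
def geometry() -> BarnGeometry:
    return BarnGeometry()


@pytest.fixture(scope="session")
def grid() -> GridSpec:
    return GridSpec()


def make_traj(xs, ys, *, cow_id="c1", start="2021-03-01 00:00:00", step_s=8.0):
    """Build a trajectory with evenly spaced timestamps."""
    n = len(xs)
    ts = pd.Timestamp(start) + pd.to_timedelta(np.arange(n) * step_s, unit="s")
    return Trajectory(
        cow_id, pd.DataFrame({"timestamp": ts, "x": list(xs), "y": list(ys)})
    )


@pytest.fixture
def traj_factory():
    return make_traj


@pytest.fixture(scope="session")
def small_herd(geometry):
    """A small simulated herd shared across tests (3 cows, 2 days)."""
    from barnspace.simulate import SimulationParams, generate_herd

    params = SimulationParams(n_cows=3, n_days=2, sample_rate=0.0625, seed=11)
    trajectories, metadata = generate_herd(params, geometry)
    return params, trajectories, metadata
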