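import numpy as np
import pandas as pd
import pytest

from oligopath import synthetic as sy
from oligopath.md import TrajectoryFrames

#: planted backbone hydrogen bonds used by the small fixture
HBOND_PAIRS = ((("B", 35), ("A", 35)), (("C", 36), ("B", 36)))


@pytest.fixture(scope="session")
def toy_system_5000():
    """5000-frame toy tetramer-in-micelle trajectory with planted hole fills.

    Fill rates follow the study conditions the toy emulates: 0.3 for the
    type II/III holes and 0.1 for type I/IV.
    """
    recipe = sy.ToySystemRecipe(n_frames=5000, seed=20260)
    traj, truth, holes = sy.gen_toy_system(recipe)
    return recipe, traj, truth, holes


@pytest.fixture(scope="session")
def toy_system_small():
    """Short trajectory with planted hydrogen bonds and hole fills."""
    recipe = sy.ToySystemRecipe(n_frames=60, seed=7, planted_hbonds=HBOND_PAIRS)
    traj, truth, holes = sy.gen_toy_system(recipe)
    return recipe, traj, truth, holes


def make_traj(rows, coords, n_frames=1, times=None):
    """Assemble a TrajectoryFrames from explicit atom rows and coordinates."""
    base = np.asarray(coords, dtype=float)
    stack = np.broadcast_to(base, (n_frames,) + base.shape).copy()
    if times is None:
        times = np.arange(n_frames, dtype=float)
    return TrajectoryFrames(topology=pd.DataFrame(rows), coords=stack, times=times)
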