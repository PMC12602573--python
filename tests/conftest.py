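import numpy as np
import pytest

from cbmeta.io import BrainGrid, Experiment, Focus, ellipsoid_grid


@pytest.fixture(scope="session")
def small_grid() -> BrainGrid:
    """20^3 voxel ellipsoid at 4 mm — the toy grid for null-distribution tests."""
    return ellipsoid_grid(shape=(20, 20, 20), voxel_size_mm=4.0)


@pytest.fixture(scope="session")
def sim_grid() -> BrainGrid:
    """Default compact simulation grid (30x36x30 at 4 mm)."""
    return ellipsoid_grid()


@pytest.fixture()
def toy_experiments(small_grid):
    """Three experiments with random in-mask foci; fixed seed."""
    rng = np.random.default_rng(7)
    mm = small_grid.mask_voxel_centers_mm()
    return [
        Experiment(f"S{i}", f"E{i}", n=20,
                   foci=[Focus(*mm[j]) for j in rng.integers(0, len(mm), 10)])
        for i in range(3)
    ]
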