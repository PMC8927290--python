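import numpy as np
import pytest

from dosekit.grid import VoxelGrid
from dosekit.phantom import PhantomParams, generate_phantom
from dosekit.plans import PlanSpec


SMALL_SHAPE = (32, 32, 16)
SMALL_SPACING = (5.0, 5.0, 5.0)


@pytest.fixture(scope="session")
def small_grid() -> VoxelGrid:
    return VoxelGrid.centered(SMALL_SHAPE, SMALL_SPACING)


@pytest.fixture(scope="session")
def small_phantom():
    """Noise-free desk-scale phantom shared by read-only tests."""
    params = PhantomParams(
        shape=SMALL_SHAPE, spacing_mm=SMALL_SPACING, noise_sd_hu=0.0, seed=7
    )
    return generate_phantom(params)


@pytest.fixture(scope="session")
def seven_beam_plan() -> PlanSpec:
    return PlanSpec(angles=(0.0, 50.0, 100.0, 150.0, 210.0, 260.0, 310.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
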