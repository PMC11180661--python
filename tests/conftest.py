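import numpy as np
import pytest

from dentseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec():
    """Physically realistic phantom on a coarse grid (fast to rasterize).

    Same mm geometry as the default spec; half the grid resolution via
    doubled spacing, so every invariant (implant fit, containment) holds.
    """
    return PhantomSpec(grid_shape=(40, 56, 68),
                       voxel_spacing_mm=(0.6, 0.6, 0.6), seed=4)


@pytest.fixture(scope="session")
def small_case(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def default_case():
    """One phantom at the standardized clinical grid, 79 x 112 x 135."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
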