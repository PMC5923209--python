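import numpy as np
import pytest

import cardiohelix as ch


@pytest.fixture(scope="session")
def small_spec():
    """Coarse isotropic phantom: 24-voxel grid, 6-voxel wall."""
    return ch.PhantomSpec(shape=(24, 24, 6), spacing=(125.0, 125.0, 125.0),
                          endo_radius_um=500.0, epi_radius_um=1250.0)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    geom = ch.make_lv_geometry(small_spec)
    fibers, gt = ch.make_fiber_field(geom, small_spec)
    return small_spec, geom, fibers, gt


@pytest.fixture(scope="session")
def medium_spec():
    """Isotropic 48-grid phantom with a 12-voxel wall (standard test size)."""
    return ch.PhantomSpec(shape=(48, 48, 16), spacing=(125.0, 125.0, 125.0),
                          endo_radius_um=750.0, epi_radius_um=2250.0)


@pytest.fixture(scope="session")
def medium_phantom(medium_spec):
    geom = ch.make_lv_geometry(medium_spec)
    fibers, gt = ch.make_fiber_field(geom, medium_spec)
    return medium_spec, geom, fibers, gt


@pytest.fixture(scope="session")
def medium_dwi(medium_phantom):
    spec, geom, fibers, gt = medium_phantom
    stack, protocol = ch.synthesize_dwi(fibers, geom, spec, ground_truth=gt)
    return stack, protocol


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
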