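import numpy as np
import pytest

import petacval as pv


@pytest.fixture(scope="session")
def small_bundle():
    """A desk-scale phantom small enough for per-test reconstruction."""
    return pv.generate_phantom(seed=1, grid=(64, 64, 4), spacing=(2.0, 2.0, 2.0), n_rois=4)


@pytest.fixture(scope="session")
def small_geometry(small_bundle):
    # FOV 96*2=192 mm covers the 64*2 mm grid's 181 mm diagonal
    return pv.SinoGeometry.for_volume(small_bundle.activity, n_radial=96,
                                      radial_spacing=2.0, n_angles=48)


@pytest.fixture(scope="session")
def small_model(small_bundle, small_geometry):
    return pv.AcquisitionModel(
        small_geometry,
        pv.compute_acf(small_bundle.mu_ct, small_geometry),
        pv.make_normalization(small_geometry),
        scatter_fraction=0.3,
        duration_scale=0.3,
    )


@pytest.fixture(scope="session")
def default_bundle():
    """The full-default phantom (128x128x16 at 2 mm, 8 ROIs)."""
    return pv.generate_phantom(seed=1)


def uniform_disc_mu(n=128, spacing=2.0, nz=4, mu=0.0096, radius=100.0):
    """Anti-aliased uniform-μ disc volume centered on the grid."""
    grid = pv.VoxelVolume(np.zeros((n, n, nz)), (spacing, spacing, spacing))
    cx, cy, _ = grid.center_world()
    disc = pv.rasterize_disc(grid, (cx, cy), radius, supersample=4)
    return grid.copy_with(mu * disc.data)
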