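import numpy as np
import pytest

import petacval as pv
from petacval.projection import Sinogram, SinoGeometry

from conftest import uniform_disc_mu


def random_pair(geometry, shape, spacing, seed):
    rng = np.random.default_rng(seed)
    x = pv.VoxelVolume(rng.random(shape), spacing)
    y = Sinogram(rng.random(geometry.shape), geometry)
    return x, y


class TestForwardProject:
    def test_disc_chord_lengths_match_closed_form(self):
        """Line integrals through a uniform disc equal v·2·sqrt(R²−r²)."""
        mu = uniform_disc_mu(n=128, spacing=2.0, nz=2, mu=1.0, radius=50.0)
        geo = SinoGeometry(n_radial=185, radial_spacing=2.0, n_angles=8,
                          n_slices=2, slice_spacing=2.0)
        sino = pv.forward_project(mu, geo)
        r = geo.radial_offsets
        inside = np.abs(r) <= 45.0  # stay off the tangent rays
        chord = 2.0 * np.sqrt(np.clip(50.0**2 - r[inside] ** 2, 0, None))
        for ia in range(geo.n_angles):
            np.testing.assert_allclose(sino.data[ia, inside, 0], chord, rtol=0.01)

    def test_linearity(self, small_bundle, small_geometry):
        rng = np.random.default_rng(0)
        shape = small_bundle.activity.shape
        x = small_bundle.activity.copy_with(rng.random(shape))
        y = small_bundle.activity.copy_with(rng.random(shape))
        ax = pv.forward_project(x, small_geometry).data
        ay = pv.forward_project(y, small_geometry).data
        combo = small_bundle.activity.copy_with(2.5 * x.data - 0.5 * y.data)
        np.testing.assert_allclose(
            pv.forward_project(combo, small_geometry).data, 2.5 * ax - 0.5 * ay,
            rtol=1e-12, atol=1e-9,
        )

    def test_zero_volume_gives_zero_sinogram(self, small_bundle, small_geometry):
        z = small_bundle.activity.copy_with(np.zeros(small_bundle.activity.shape))
        assert pv.forward_project(z, small_geometry).data.sum() == 0

    def test_point_source_constant_across_angles(self):
        vol = pv.VoxelVolume(np.zeros((64, 64, 1)), (2.0, 2.0, 2.0))
        c = vol.center_world()
        # small PSF-like blob at the exact center avoids pure-delta aliasing
        blob = pv.rasterize_sphere(vol, c, 4.0, supersample=3)
        geo = SinoGeometry(96, 2.0, 24, 1, 2.0)
        sino = pv.forward_project(blob, geo)
        per_angle_max = sino.data[:, :, 0].max(axis=1)
        assert per_angle_max.std() / per_angle_max.mean() < 0.02

    def test_fov_too_small_rejected(self):
        vol = pv.VoxelVolume(np.zeros((64, 64, 1)), (2.0, 2.0, 2.0))
        geo = SinoGeometry(32, 2.0, 8, 1, 2.0)  # 64 mm FOV < 181 mm diagonal
        with pytest.raises(ValueError, match="FOV"):
            pv.forward_project(vol, geo)

    def test_mismatched_slice_count_rejected(self, small_bundle):
        geo = SinoGeometry(96, 2.0, 8, n_slices=9, slice_spacing=2.0)
        with pytest.raises(ValueError, match="slices"):
            pv.forward_project(small_bundle.activity, geo)


class TestAdjointness:
    @pytest.mark.parametrize("n,n_angles", [(64, 48), (32, 16), (48, 24)])
    def test_forward_back_adjoint_identity(self, n, n_angles):
        geo = SinoGeometry(2 * n, 2.0, n_angles, 4, 2.0)
        shape, spacing = (n, n, 4), (2.0, 2.0, 2.0)
        for seed in range(5):
            x, y = random_pair(geo, shape, spacing, seed)
            lhs = float((pv.forward_project(x, geo).data * y.data).sum())
            rhs = float((x.data * pv.back_project(y, x).data).sum())
            assert abs(lhs - rhs) <= 1e-6 * abs(lhs)

    def test_backprojection_positive_inside_fov(self, small_bundle, small_geometry):
        ones = Sinogram(np.ones(small_geometry.shape), small_geometry)
        bp = pv.back_project(ones, small_bundle.activity)
        n = small_bundle.activity.shape[0]
        interior = bp.data[n // 4 : -n // 4, n // 4 : -n // 4, :]
        assert (interior > 0).all()

    def test_backprojection_of_zero_is_zero(self, small_bundle, small_geometry):
        z = Sinogram(np.zeros(small_geometry.shape), small_geometry)
        assert pv.back_project(z, small_bundle.activity).data.sum() == 0


class TestComputeAcf:
    def test_uniform_disc_closed_form(self):
        mu = uniform_disc_mu(n=128, spacing=2.0, nz=1, mu=0.0096, radius=100.0)
        geo = SinoGeometry(191, 2.0, 4, 1, 2.0)
        acf = pv.compute_acf(mu, geo)
        central = acf.data[:, 95, 0]  # radial offset exactly 0
        np.testing.assert_allclose(central, np.exp(0.0096 * 200.0), rtol=0.01)

    def test_skull_like_annulus_two_chord_value(self):
        """Soft disc with a bone annulus: acf = exp(μs·Ls + μb·Lb) on the diameter."""
        mu_s, mu_b = 0.0096, 0.0151
        soft = uniform_disc_mu(128, 2.0, 1, 1.0, 100.0).data
        outer = uniform_disc_mu(128, 2.0, 1, 1.0, 90.0).data
        inner = uniform_disc_mu(128, 2.0, 1, 1.0, 80.0).data
        mu = pv.VoxelVolume(mu_s * soft + (mu_b - mu_s) * (outer - inner), (2.0, 2.0, 2.0))
        geo = SinoGeometry(191, 2.0, 4, 1, 2.0)
        acf = pv.compute_acf(mu, geo)
        bone_len, soft_len = 2 * (90.0 - 80.0), 200.0 - 2 * (90.0 - 80.0)
        expected = np.exp(mu_s * soft_len + mu_b * bone_len)
        np.testing.assert_allclose(acf.data[:, 95, 0], expected, rtol=0.01)

    def test_zero_mu_gives_unit_acf(self):
        vol = pv.VoxelVolume(np.zeros((64, 64, 2)), (2.0, 2.0, 2.0))
        geo = SinoGeometry(96, 2.0, 8, 2, 2.0)
        assert np.array_equal(pv.compute_acf(vol, geo).data, np.ones(geo.shape))

    def test_doubling_mu_squares_acf(self):
        mu = uniform_disc_mu(64, 2.0, 1, 0.005, 40.0)
        geo = SinoGeometry(96, 2.0, 8, 1, 2.0)
        a1 = pv.compute_acf(mu, geo).data
        a2 = pv.compute_acf(mu.copy_with(2 * mu.data), geo).data
        np.testing.assert_allclose(a2, a1**2, rtol=1e-10)

    def test_negative_mu_rejected(self):
        vol = pv.VoxelVolume(np.full((64, 64, 1), -0.001), (2.0, 2.0, 2.0))
        geo = SinoGeometry(96, 2.0, 8, 1, 2.0)
        with pytest.raises(ValueError, match="negative"):
            pv.compute_acf(vol, geo)


class TestNormalization:
    def test_uniform_is_all_ones(self):
        geo = SinoGeometry(32, 2.0, 8, 2, 2.0)
        assert np.array_equal(pv.make_normalization(geo).data, np.ones(geo.shape))

    def test_seeded_efficiency_bounds_and_determinism(self):
        geo = SinoGeometry(32, 2.0, 8, 2, 2.0)
        n1 = pv.make_normalization(geo, "seeded_efficiency", seed=3)
        n2 = pv.make_normalization(geo, "seeded_efficiency", seed=3)
        assert np.array_equal(n1.data, n2.data)
        assert n1.data.min() >= 0.9 and n1.data.max() <= 1.1


class TestSinogramRoles:
    def test_role_invariants_enforced(self):
        geo = SinoGeometry(8, 2.0, 4, 1, 2.0)
        with pytest.raises(ValueError, match="non-negative"):
            Sinogram(-np.ones(geo.shape), geo, "counts")
        with pytest.raises(ValueError, match="integers"):
            Sinogram(np.full(geo.shape, 0.5), geo, "counts")
        with pytest.raises(ValueError, match=">= 1"):
            Sinogram(np.full(geo.shape, 0.5), geo, "acf")
        with pytest.raises(ValueError, match="> 0"):
            Sinogram(np.zeros(geo.shape), geo, "normalization")
        with pytest.raises(ValueError, match="unknown sinogram role"):
            Sinogram(np.ones(geo.shape), geo, "trues")
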