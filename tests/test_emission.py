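import numpy as np
import pytest

import petacval as pv
from petacval.emission import (
    AcquisitionModel,
    LesionSpec,
    add_poisson,
    compose,
    expected_counts,
    expected_counts_split,
    lesion_activity_volume,
    lesion_mask,
    lesion_support_mask,
)
from petacval.projection import Sinogram, SinoGeometry


class TestLesionSpec:
    def test_rule_exclusivity(self):
        with pytest.raises(ValueError, match="exactly one"):
            LesionSpec.sphere((0, 0, 0), 4.0)
        with pytest.raises(ValueError, match="exactly one"):
            LesionSpec.sphere((0, 0, 0), 4.0, absolute=1.0, lbr=2.0)

    def test_geometry_validation(self):
        with pytest.raises(ValueError, match="radius"):
            LesionSpec.sphere((0, 0, 0), -1.0, absolute=1.0)
        with pytest.raises(ValueError, match="ratio"):
            LesionSpec.sphere((0, 0, 0), 4.0, lbr=-2.0)


class TestLesionActivityVolume:
    def test_absolute_without_psf_is_exact(self, small_bundle):
        c = small_bundle.activity.center_world()
        spec = LesionSpec.sphere(c, 6.0, absolute=10.0, psf_fwhm=0.0)
        vol = lesion_activity_volume(spec, small_bundle.atlas)
        mask = lesion_mask(spec, small_bundle.atlas).data.astype(bool)
        assert np.array_equal(vol.data, 10.0 * mask)

    def test_lbr_scales_background_mean(self, small_bundle):
        b = small_bundle
        label = b.brain_labels(near_skull=False)[0]
        spec = LesionSpec.atlas_roi(label, lbr=2.0, psf_fwhm=0.0)
        vol = lesion_activity_volume(spec, b.atlas, b.activity)
        mask = b.atlas.data == label
        bg_mean = b.activity.data[mask].mean()
        assert vol.data[mask].max() == pytest.approx(2.0 * bg_mean)

    def test_psf_preserves_total_activity(self, small_bundle):
        c = small_bundle.activity.center_world()
        spec = LesionSpec.sphere(c, 6.0, absolute=5.0, psf_fwhm=4.0)
        smoothed = lesion_activity_volume(spec, small_bundle.atlas)
        sharp = lesion_activity_volume(
            LesionSpec.sphere(c, 6.0, absolute=5.0, psf_fwhm=0.0), small_bundle.atlas
        )
        assert smoothed.data.sum() == pytest.approx(sharp.data.sum(), rel=0.005)

    def test_lbr_requires_background(self, small_bundle):
        spec = LesionSpec.atlas_roi(small_bundle.brain_labels()[0], lbr=2.0)
        with pytest.raises(ValueError, match="background"):
            lesion_activity_volume(spec, small_bundle.atlas)

    def test_missing_label_rejected(self, small_bundle):
        spec = LesionSpec.atlas_roi(999, absolute=1.0)
        with pytest.raises(ValueError, match="not present"):
            lesion_activity_volume(spec, small_bundle.atlas)


class TestExpectedCounts:
    def test_degenerate_chain_is_scaled_line_integrals(self, small_bundle, small_geometry):
        geo = small_geometry
        zero_mu = small_bundle.mu_ct.copy_with(np.zeros(small_bundle.mu_ct.shape))
        model = AcquisitionModel(
            geo, pv.compute_acf(zero_mu, geo), pv.make_normalization(geo),
            scatter_fraction=0.0, duration_scale=2.0,
        )
        exp = expected_counts(small_bundle.activity, model)
        li = pv.forward_project(small_bundle.activity, geo)
        np.testing.assert_allclose(exp.data, 2.0 * li.data, rtol=1e-12)

    def test_global_scatter_fraction_is_exact(self, small_bundle, small_model):
        trues, scatter = expected_counts_split(small_bundle.activity, small_model)
        frac = scatter.data.sum() / (trues.data.sum() + scatter.data.sum())
        assert frac == pytest.approx(small_model.scatter_fraction, abs=1e-6)

    def test_duration_scale_linearity(self, small_bundle, small_geometry, small_model):
        doubled = AcquisitionModel(
            small_geometry, small_model.acf, small_model.norm,
            small_model.scatter_fraction, 2 * small_model.duration_scale,
        )
        e1 = expected_counts(small_bundle.activity, small_model)
        e2 = expected_counts(small_bundle.activity, doubled)
        np.testing.assert_allclose(e2.data, 2 * e1.data, rtol=1e-12)

    def test_expectation_linearity_in_activity(self, small_bundle, small_model):
        a = small_bundle.activity
        half = a.copy_with(0.5 * a.data)
        e_full = expected_counts(a, small_model)
        e_half = expected_counts(half, small_model)
        np.testing.assert_allclose(e_full.data, 2 * e_half.data, rtol=1e-10)


class TestAddPoisson:
    def test_zero_expectation_gives_zero_counts(self):
        geo = SinoGeometry(16, 2.0, 4, 1, 2.0)
        expected = Sinogram(np.zeros(geo.shape), geo, "expected_counts")
        assert add_poisson(expected, seed=1).data.sum() == 0

    def test_moments_at_expectation_100(self):
        """10⁵ bins at expectation 100: mean and variance behave as Poisson."""
        geo = SinoGeometry(100, 2.0, 100, 10, 2.0)
        expected = Sinogram(np.full(geo.shape, 100.0), geo, "expected_counts")
        counts = add_poisson(expected, seed=12345).data
        n = counts.size
        assert n == 10**5
        assert abs(counts.mean() - 100.0) <= 3 * np.sqrt(100.0 / n)
        assert 0.97 <= counts.var(ddof=1) / counts.mean() <= 1.03

    def test_seed_determinism(self):
        geo = SinoGeometry(16, 2.0, 8, 2, 2.0)
        expected = Sinogram(np.full(geo.shape, 7.0), geo, "expected_counts")
        assert np.array_equal(add_poisson(expected, 9).data, add_poisson(expected, 9).data)


class TestCompose:
    def setup_method(self):
        self.geo = SinoGeometry(32, 2.0, 8, 2, 2.0)
        rng = np.random.default_rng(0)
        self.background = Sinogram(
            rng.poisson(20.0, self.geo.shape).astype(np.int64), self.geo, "counts"
        )
        lesion = np.zeros(self.geo.shape)
        lesion[:, 10:16, :] = 5.0
        self.lesion = Sinogram(lesion, self.geo, "expected_counts")

    def test_zero_lesion_add_is_identity(self):
        zero = self.lesion.copy_with(np.zeros(self.geo.shape))
        out = compose(self.background, zero, "add", seed=1)
        assert np.array_equal(out.data, self.background.data)

    def test_lesion_only_ignores_background(self):
        a = compose(self.background, self.lesion, "lesion_only", seed=4)
        b = compose(None, self.lesion, "lesion_only", seed=4)
        assert np.array_equal(a.data, b.data)

    def test_add_total_is_exact_integer_accounting(self):
        out = compose(self.background, self.lesion, "add", seed=2)
        draw = add_poisson(self.lesion, seed=2)
        assert out.data.sum() == self.background.data.sum() + draw.data.sum()

    def test_replace_touches_only_support(self):
        out = compose(self.background, self.lesion, "replace", seed=3)
        mask = lesion_support_mask(self.lesion)
        assert np.array_equal(out.data[~mask], self.background.data[~mask])
        assert not np.array_equal(out.data[mask], self.background.data[mask])

    def test_add_without_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            compose(None, self.lesion, "add", seed=1)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            compose(self.background, self.lesion, "subtract", seed=1)
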