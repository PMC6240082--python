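"""FRC resolution, FOI effective PSF and the contrast statistic."""

import numpy as np
import pandas as pd
import pytest

from qstorm import QuenchModel, quench_efficiency
from qstorm.experiments import simulate_fibre_table
from qstorm.inference import RegionMask
from qstorm.metrics import (
    contrast,
    foi,
    frc,
    frc_from_images,
    improvement_factor,
)
from qstorm.photophysics import AcquisitionParams, simulate_acquisition
from qstorm.render import SRImage, render_sr
from qstorm.scene import Fibre, SceneGeometry, place_fluorophores


class TestFRC:
    def test_identical_half_sets_fully_correlated(self):
        rng = np.random.default_rng(0)
        img = rng.poisson(5.0, (128, 128)).astype(float)
        res = frc_from_images(img, img.copy(), pixel_nm=10.0)
        np.testing.assert_allclose(res.correlation[1:], 1.0, atol=1e-9)

    def test_independent_noise_decorrelates_at_high_frequency(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(5.0, (128, 128)).astype(float)
        b = rng.poisson(5.0, (128, 128)).astype(float)
        res = frc_from_images(a, b, pixel_nm=10.0)
        high = res.correlation[len(res.correlation) // 2 :]
        assert np.abs(high).mean() < 0.05

    def test_resolution_invariant_under_translation(self, fibre_scene):
        table = simulate_fibre_table(
            fibre_scene.fibres, locs_per_um=4000, sigma_loc_nm=8.0, seed=3,
            field_size=fibre_scene.field_size,
        )
        base = frc(table, pixel_nm=5.0, seed=7, field_size=(4200.0, 4200.0))
        moved = table.assign(x_nm=table["x_nm"] + 100.0, y_nm=table["y_nm"] + 100.0)
        shifted = frc(moved, pixel_nm=5.0, seed=7, field_size=(4200.0, 4200.0))
        assert shifted.resolution_nm == pytest.approx(base.resolution_nm, rel=0.02)

    def test_split_is_bit_stable_for_fixed_seed(self, fibre_scene):
        table = simulate_fibre_table(
            fibre_scene.fibres, locs_per_um=2000, sigma_loc_nm=8.0, seed=3,
            field_size=fibre_scene.field_size,
        )
        r1 = frc(table, pixel_nm=5.0, seed=5, field_size=fibre_scene.field_size)
        r2 = frc(table, pixel_nm=5.0, seed=5, field_size=fibre_scene.field_size)
        assert r1.resolution_nm == r2.resolution_nm
        np.testing.assert_array_equal(r1.correlation, r2.correlation)

    def test_unresolvable_data_flagged_not_raised(self):
        # two independent sparse noise tables: correlation starts below 1/7
        rng = np.random.default_rng(2)
        table = pd.DataFrame(
            {
                "frame": 1,
                "x_nm": rng.uniform(0, 5000, 300),
                "y_nm": rng.uniform(0, 5000, 300),
                "sigma_nm": 150.0,
                "photons": 500.0,
                "uncertainty_nm": 8.0,
            }
        )
        res = frc(table, pixel_nm=50.0, seed=1, field_size=(5000.0, 5000.0))
        assert res.resolved in (True, False)  # never raises
        if not res.resolved:
            assert np.isnan(res.resolution_nm)

    def test_too_few_localizations_rejected(self):
        table = pd.DataFrame({"frame": [1], "x_nm": [1.0], "y_nm": [1.0],
                              "photons": [10.0], "uncertainty_nm": [5.0],
                              "sigma_nm": [150.0]})
        with pytest.raises(ValueError):
            frc(table, pixel_nm=5.0, seed=0)


def _straight_backbone(y=2000.0, x0=200.0, x1=3800.0):
    return np.column_stack([np.linspace(x0, x1, 50), np.full(50, y)])


class TestFOI:
    def test_zero_width_fibre_recovers_psf_directly(self):
        """With no fibre or fluorophore size to subtract, FOI returns the
        profile FWHM itself."""
        bb = _straight_backbone()
        fib = Fibre(points=tuple(map(tuple, bb)), width_nm=0.5)
        w = 40.0
        table = simulate_fibre_table(
            [fib], locs_per_um=4000, sigma_loc_nm=None, transverse_fwhm_nm=w,
            seed=4, field_size=(4000.0, 4000.0),
        )
        res = foi(table, backbones=[bb], fibre_width_nm=0.0, fluorophore_nm=0.0,
                  bin_nm=4.0, render_pixel_nm=4.0, expected_psf_fwhm_nm=w)
        assert res.effective_psf_nm == pytest.approx(w, abs=4.0)

    def test_invariant_under_intensity_rescaling(self):
        bb = _straight_backbone()
        fib = Fibre(points=tuple(map(tuple, bb)), width_nm=11.0)
        table = simulate_fibre_table(
            [fib], locs_per_um=3000, sigma_loc_nm=None, transverse_fwhm_nm=50.0,
            seed=5, field_size=(4000.0, 4000.0),
        )
        img = render_sr(table, 4.0, "gaussian", field_size=(4000.0, 4000.0))
        scaled = SRImage(img.pixels * 37.5, img.pixel_nm, provenance=img.provenance)
        a = foi(img, backbones=[bb], expected_psf_fwhm_nm=38.0)
        b = foi(scaled, backbones=[bb], expected_psf_fwhm_nm=38.0)
        np.testing.assert_allclose(a.fwhm_values_nm, b.fwhm_values_nm, rtol=1e-6)
        assert a.modal_fwhm_nm == b.modal_fwhm_nm

    def test_flat_image_reports_failures(self):
        img = SRImage(np.zeros((100, 100)), 10.0)
        with pytest.raises(RuntimeError, match="profile fits"):
            foi(img, backbones=[_straight_backbone(y=500.0, x1=900.0)],
                expected_psf_fwhm_nm=40.0)

    def test_negative_effective_psf_flagged(self):
        bb = _straight_backbone()
        fib = Fibre(points=tuple(map(tuple, bb)), width_nm=0.5)
        table = simulate_fibre_table(
            [fib], locs_per_um=4000, sigma_loc_nm=None, transverse_fwhm_nm=20.0,
            seed=6, field_size=(4000.0, 4000.0),
        )
        res = foi(table, backbones=[bb], fibre_width_nm=30.0, fluorophore_nm=1.0,
                  bin_nm=4.0, render_pixel_nm=4.0, expected_psf_fwhm_nm=20.0)
        assert res.negative_psf


class TestContrast:
    def _image(self, feature_value, background_value):
        px = np.full((100, 100), float(background_value))
        px[40:60, :] = feature_value
        img = SRImage(px, 10.0)
        feat = RegionMask.from_rect(0, 400.0, 1000.0, 600.0, label="feature")
        bg = RegionMask.from_rect(0, 0, 1000.0, 300.0, label="background")
        return img, feat, bg

    def test_equal_intensities_give_zero(self):
        img, feat, bg = self._image(5.0, 5.0)
        assert contrast(img, feat, bg).c == pytest.approx(0.0)

    def test_double_intensity_gives_one(self):
        img, feat, bg = self._image(10.0, 5.0)
        assert contrast(img, feat, bg).c == pytest.approx(1.0)

    def test_invariant_under_global_rescaling(self):
        img, feat, bg = self._image(42.0, 6.0)
        scaled = SRImage(img.pixels * 11.0, img.pixel_nm)
        assert contrast(scaled, feat, bg).c == pytest.approx(contrast(img, feat, bg).c)

    def test_zero_background_is_explicit_failure(self):
        img, feat, bg = self._image(5.0, 0.0)
        with pytest.raises(ZeroDivisionError):
            contrast(img, feat, bg)

    def test_overlapping_masks_rejected(self):
        img, feat, _ = self._image(5.0, 1.0)
        with pytest.raises(ValueError, match="overlap"):
            contrast(img, feat, feat)

    def test_go_quenching_boosts_contrast_by_suppression_factor(self, cy3b_model):
        """Quenching the background by (1 - eps) multiplies C by ~1/(1 - eps)
        when the feature is much brighter than the background."""
        bb = _straight_backbone(y=1000.0, x0=100.0, x1=2900.0)
        scene = SceneGeometry(
            field_size=(3000.0, 2000.0),
            fibres=[Fibre(points=tuple(map(tuple, bb)), width_nm=11.0)],
        )
        labels = place_fluorophores(
            scene, {"specific": 1e5}, spacer_thickness_nm=20.0, seed=1,
            photon_budget_mean=500.0,
        )
        background = place_fluorophores(
            scene, {"nonspecific_background": 100.0}, spacer_thickness_nm=2.0,
            seed=2, photon_budget_mean=500.0,
        )
        placements = labels + background
        params = AcquisitionParams(n_frames=100, p_on=0.05,
                                   detection_threshold_photons=0.0)
        feat = RegionMask.from_rect(100.0, 975.0, 2900.0, 1025.0, label="feature")
        bg = RegionMask.from_rect(100.0, 100.0, 2900.0, 800.0, label="background")

        def run(over_go):
            member = lambda x, y: np.full(np.shape(np.asarray(x)), over_go, bool)  # noqa: E731
            table = simulate_acquisition(placements, cy3b_model, params, member, seed=3)
            return contrast(table, feat, bg).c

        c_without, c_with = run(False), run(True)
        suppression = 1.0 / (1.0 - quench_efficiency(2.0, cy3b_model))
        assert improvement_factor(c_with, c_without, "contrast_ratio") == pytest.approx(
            suppression, rel=0.3
        )


class TestImprovementFactor:
    def test_printed_contrast_ratio(self):
        assert improvement_factor(133.0, 13.0, "contrast_ratio") == pytest.approx(
            10.23, abs=0.01
        )

    def test_printed_resolution_percent(self):
        assert improvement_factor(19.0, 23.0, "resolution_percent") == pytest.approx(
            21.05, abs=0.01
        )

    def test_printed_psf_ratio(self):
        assert improvement_factor(24.0, 56.0, "psf_ratio") == pytest.approx(2.33, abs=0.01)

    def test_equal_inputs_are_neutral(self):
        assert improvement_factor(5.0, 5.0, "contrast_ratio") == 1.0
        assert improvement_factor(5.0, 5.0, "resolution_percent") == 0.0
        assert improvement_factor(5.0, 5.0, "psf_ratio") == 1.0

    def test_contrast_ratio_composes_multiplicatively(self):
        """Serial background suppressions multiply."""
        step1 = improvement_factor(40.0, 10.0, "contrast_ratio")
        step2 = improvement_factor(120.0, 40.0, "contrast_ratio")
        total = improvement_factor(120.0, 10.0, "contrast_ratio")
        assert step1 * step2 == pytest.approx(total)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            improvement_factor(1.0, 0.0, "contrast_ratio")
        with pytest.raises(ValueError):
            improvement_factor(1.0, 1.0, "nonsense")
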