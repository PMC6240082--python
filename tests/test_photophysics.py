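"""Quenching law, blinking simulation and the photon-route estimator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from qstorm import QuenchModel, invert_quench, quench_efficiency
from qstorm.photophysics import AcquisitionParams, simulate_acquisition
from qstorm.scene import FluorophorePlacement


def _always(value):
    def member(x, y):
        return np.full(np.shape(np.asarray(x)), value, dtype=bool)

    return member


class TestQuenchLaw:
    def test_efficiency_at_quenching_range_edge(self, cy3b_model):
        # ~5 % at the 15 nm edge of the efficient quenching range
        assert quench_efficiency(15.0, cy3b_model) == pytest.approx(0.05143, abs=1e-4)

    def test_efficiency_near_contact(self, cy3b_model):
        assert quench_efficiency(2.0, cy3b_model) == pytest.approx(0.9942, abs=1e-4)

    def test_zero_coupling_means_no_quenching(self):
        model = QuenchModel(a=0.0, wavelength_nm=570.0)
        assert quench_efficiency(5.0, model) == 0.0

    def test_nonpositive_gap_rejected(self, cy3b_model):
        with pytest.raises(ValueError):
            quench_efficiency(0.0, cy3b_model)

    @given(
        z1=st.floats(0.5, 100.0),
        z2=st.floats(0.5, 100.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_strictly_decreasing_in_z(self, z1, z2):
        model = QuenchModel(a=2.6e-8, wavelength_nm=570.0)
        if abs(z1 - z2) < 1e-6:
            return
        lo, hi = sorted([z1, z2])
        assert quench_efficiency(lo, model) > quench_efficiency(hi, model)

    @given(st.floats(1e-10, 1e-6), st.floats(100.0, 800.0), st.floats(0.5, 50.0))
    @settings(deadline=None, max_examples=50)
    def test_increasing_in_coupling_and_wavelength(self, a, lam, z):
        base = quench_efficiency(z, QuenchModel(a=a, wavelength_nm=lam))
        assert quench_efficiency(z, QuenchModel(a=2 * a, wavelength_nm=lam)) > base
        assert quench_efficiency(z, QuenchModel(a=a, wavelength_nm=1.5 * lam)) > base


class TestInvertQuench:
    def test_half_efficiency_gap(self, cy3b_model):
        # z(1/2) = lambda A^(1/4)
        assert invert_quench(0.5, cy3b_model) == pytest.approx(
            570.0 * 2.6e-8**0.25, rel=1e-12
        )

    @given(st.floats(0.6, 30.0))
    @settings(deadline=None, max_examples=50)
    def test_round_trip_identity(self, z):
        model = QuenchModel(a=2.6e-8, wavelength_nm=570.0)
        eps = quench_efficiency(z, model)
        assert invert_quench(eps, model) == pytest.approx(z, rel=1e-10)

    def test_gap_vanishes_as_efficiency_approaches_one(self, cy3b_model):
        zs = [invert_quench(e, cy3b_model) for e in (0.9, 0.99, 0.999, 0.999999)]
        assert all(a > b for a, b in zip(zs, zs[1:]))
        assert zs[-1] < 1.0

    def test_domain_errors(self, cy3b_model):
        for bad in (0.0, 1.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                invert_quench(bad, cy3b_model)
        with pytest.raises(ValueError):
            invert_quench(0.5, QuenchModel(a=0.0))


class TestSimulateAcquisition:
    def test_always_on_fluorophore_detected_every_frame(self, cy3b_model):
        placements = [FluorophorePlacement(500.0, 500.0, 20.0, photon_budget_mean=1000.0)]
        params = AcquisitionParams(
            n_frames=100, p_on=1.0, detection_threshold_photons=0.0,
            background_photons_per_pixel=0.0,
        )
        table = simulate_acquisition(placements, cy3b_model, params, _always(False), seed=1)
        assert len(table) == 100
        assert set(table["frame"]) == set(range(1, 101))
        se = np.sqrt(1000.0 / 100)
        assert table["photons"].mean() == pytest.approx(1000.0, abs=3 * se)

    def test_strong_quenching_suppresses_detections(self, cy3b_model):
        # over GO at z=2 nm: (1 - eps) ~ 0.006, expected ~6 photons << 50
        placements = [FluorophorePlacement(500.0, 500.0, 2.0, photon_budget_mean=1000.0)]
        params = AcquisitionParams(
            n_frames=200, p_on=1.0, detection_threshold_photons=50.0
        )
        table = simulate_acquisition(placements, cy3b_model, params, _always(True), seed=2)
        assert len(table) == 0

    def test_fewer_detections_over_go_than_off(self, cy3b_model):
        # off GO the budget clears the threshold, over GO (eps ~ 0.53 at
        # z = 7 nm) the attenuated count usually falls below it
        mk = lambda x: FluorophorePlacement(x, 500.0, 7.0, photon_budget_mean=150.0)  # noqa: E731
        placements = [mk(100.0), mk(900.0)]

        def member(x, y):
            return np.asarray(x) < 500.0  # left fluorophore sits over GO

        params = AcquisitionParams(n_frames=500, p_on=0.5, detection_threshold_photons=100.0)
        table = simulate_acquisition(placements, cy3b_model, params, member, seed=3)
        n_go = int((table["x_nm"] < 500.0).sum())
        n_off = int((table["x_nm"] > 500.0).sum())
        assert n_go < n_off

    def test_uncertainty_follows_inverse_sqrt_photons(self, cy3b_model):
        placements = [FluorophorePlacement(500.0, 500.0, 20.0, photon_budget_mean=400.0)]
        params = AcquisitionParams(n_frames=200, p_on=1.0, psf_sigma_nm=150.0,
                                   detection_threshold_photons=0.0)
        table = simulate_acquisition(placements, cy3b_model, params, _always(False), seed=4)
        np.testing.assert_allclose(
            table["uncertainty_nm"], 150.0 / np.sqrt(table["photons"]), rtol=1e-12
        )

    def test_empty_placements_rejected(self, cy3b_model):
        params = AcquisitionParams()
        with pytest.raises(ValueError):
            simulate_acquisition([], cy3b_model, params, _always(False), seed=0)

    def test_invalid_blinking_probability_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionParams(p_on=0.0)
        with pytest.raises(ValueError):
            AcquisitionParams(p_on=1.5)

    def test_membership_failure_is_reported(self, cy3b_model):
        placements = [FluorophorePlacement(500.0, 500.0, 7.0)]

        def broken(x, y):
            raise KeyError("no map here")

        with pytest.raises(ValueError, match="membership"):
            simulate_acquisition(placements, cy3b_model, AcquisitionParams(), broken, seed=0)

    def test_photon_route_epsilon_matches_closed_form(self, cy3b_model):
        """1 - (photon density over GO / off GO) converges to the law."""
        z = 7.0
        n_each = 400
        rng = np.random.default_rng(0)
        placements = [
            FluorophorePlacement(float(x), float(y), z, photon_budget_mean=500.0)
            for x, y in zip(rng.uniform(0, 400, n_each), rng.uniform(0, 1000, n_each))
        ] + [
            FluorophorePlacement(float(x), float(y), z, photon_budget_mean=500.0)
            for x, y in zip(rng.uniform(600, 1000, n_each), rng.uniform(0, 1000, n_each))
        ]

        def member(x, y):
            return np.asarray(x) < 500.0

        params = AcquisitionParams(n_frames=100, p_on=0.2, detection_threshold_photons=0.0)
        table = simulate_acquisition(placements, cy3b_model, params, member, seed=5)
        s_go = table.loc[table["x_nm"] < 500.0, "photons"].sum()
        s_off = table.loc[table["x_nm"] > 500.0, "photons"].sum()
        eps_hat = 1.0 - s_go / s_off
        assert eps_hat == pytest.approx(quench_efficiency(z, cy3b_model), abs=0.05)
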