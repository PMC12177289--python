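import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from prairiesense.cube import IndexMap, ThermalImage
from prairiesense.errors import DegeneracyError, PhysicsError, RangeError
from prairiesense.grids import Grid
from prairiesense.thermal import (
    AtmosphericState,
    BandResponse,
    EmissivityModel,
    emissivity_from_ndvi,
    planck_spectral,
    resample_ndvi_to_thermal,
    retrieve_lst,
    solve_atmosphere,
    tarp_emissivity,
    to_ground_brightness,
)


class TestPlanckBand:
    def test_matches_fine_grid_trapezoid_oracle(self, band):
        # independent brute-force quadrature on a 10x finer grid
        lam = np.linspace(7.5, 14.0, 6501)
        oracle = np.trapezoid(planck_spectral(lam, 300.0), lam) / (14.0 - 7.5)
        assert abs(band.radiance_exact(300.0) - oracle) / oracle < 1e-3

    def test_strictly_increasing_in_temperature(self, band):
        temps = np.linspace(260.0, 360.0, 101)
        vals = [band.radiance_exact(t) for t in temps]
        assert np.all(np.diff(vals) > 0)

    @given(st.floats(min_value=280.0, max_value=330.0))
    def test_invert_forward_identity(self, t):
        band = BandResponse()
        assert band.invert(band.radiance_exact(t)) == pytest.approx(t, abs=1e-4)

    def test_invert_matches_fine_grid_search(self, band):
        L = band.radiance_exact(285.0)
        grid = np.arange(280.0, 290.0, 0.001)
        vals = np.array([band.radiance_exact(t) for t in grid])
        brute = grid[np.argmin(np.abs(vals - L))]
        assert band.invert(L) == pytest.approx(brute, abs=0.01)

    def test_spline_path_agrees_with_exact(self, band):
        temps = np.linspace(255.0, 365.0, 57)
        spline = band.radiance(temps)
        exact = np.array([band.radiance_exact(t) for t in temps])
        assert np.allclose(spline, exact, rtol=1e-9)

    def test_invert_array_round_trip(self, band):
        temps = np.linspace(280.0, 330.0, 41)
        L = band.radiance(temps)
        got, n_missing = band.invert_array(L)
        assert n_missing == 0
        assert np.allclose(got, temps, atol=1e-4)

    def test_out_of_range_radiance(self, band):
        with pytest.raises(RangeError):
            band.invert(band.radiance_exact(band.t_min) * 0.5)
        _, n_missing = band.invert_array(np.array([0.01]))
        assert n_missing == 1

    def test_nonpositive_temperature_rejected(self, band):
        with pytest.raises(PhysicsError):
            band.radiance_exact(-1.0)


class TestTarpEmissivity:
    def test_equal_temperatures_give_unity(self):
        assert tarp_emissivity(300.0, 300.0) == 1.0

    def test_hand_value(self):
        assert tarp_emissivity(310.0, 312.5) == pytest.approx(
            (310.0 / 312.5) ** 4, abs=1e-12
        )
        assert tarp_emissivity(310.0, 312.5) == pytest.approx(0.9684, abs=5e-4)

    def test_above_unity_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            assert tarp_emissivity(305.0, 300.0) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(PhysicsError):
            tarp_emissivity(-1.0, 300.0)


class TestSolveAtmosphere:
    def _forward(self, band, atm, eps, temps):
        return [
            (
                e,
                t,
                atm.tau * (e * band.radiance_exact(t) + (1 - e) * atm.l_down)
                + atm.l_up,
            )
            for e, t in zip(eps, temps)
        ]

    def test_recovers_truth_to_1e9_relative(self, band):
        truth = AtmosphericState(tau=0.8, l_down=2.0, l_up=1.5)
        tarps = self._forward(band, truth, [0.88, 0.93, 0.97], [318.0, 322.0, 330.0])
        got = solve_atmosphere(tarps, band)
        assert got.tau == pytest.approx(0.8, rel=1e-9)
        assert got.l_down == pytest.approx(2.0, rel=1e-9)
        assert got.l_up == pytest.approx(1.5, rel=1e-9)

    def test_transparent_atmosphere_identity(self, band):
        truth = AtmosphericState(tau=1.0, l_down=0.0, l_up=0.0)
        tarps = self._forward(band, truth, [0.88, 0.93, 0.97], [318.0, 322.0, 330.0])
        got = solve_atmosphere(tarps, band)
        assert got.tau == pytest.approx(1.0, abs=1e-9)
        assert got.l_down == pytest.approx(0.0, abs=1e-9)
        assert got.l_up == pytest.approx(0.0, abs=1e-9)

    def test_identical_tarps_degenerate(self, band):
        truth = AtmosphericState(tau=0.9, l_down=1.0, l_up=1.0)
        tarps = self._forward(band, truth, [0.9, 0.9, 0.9], [300.0, 300.0, 300.0])
        with pytest.raises(DegeneracyError):
            solve_atmosphere(tarps, band)


class TestGroundBrightness:
    def _image(self, values):
        values = np.asarray(values, dtype=float)
        return ThermalImage(values=values, grid=Grid(0, 0, 1.0, *values.shape))

    def test_identity_atmosphere_unchanged(self):
        img = self._image(np.random.default_rng(0).uniform(5, 10, (4, 4)))
        out = to_ground_brightness(img, AtmosphericState(1.0, 0.0, 0.0))
        assert np.allclose(out.values, img.values)

    def test_constant_in_constant_out(self):
        img = self._image(np.full((3, 3), 8.0))
        out = to_ground_brightness(img, AtmosphericState(0.8, 2.0, 1.5))
        assert np.allclose(out.values, (8.0 - 1.5) / 0.8)

    def test_algebraic_round_trip_with_forward(self, band):
        # forward: L = tau*(eps*B(T) + (1-eps)*Ldown) + Lup
        atm = AtmosphericState(0.85, 3.0, 1.2)
        eps, T = 0.97, 305.0
        ground_truth = eps * band.radiance_exact(T) + (1 - eps) * atm.l_down
        img = self._image([[atm.tau * ground_truth + atm.l_up]])
        out = to_ground_brightness(img, atm)
        assert out.values[0, 0] == pytest.approx(ground_truth, rel=1e-12)

    def test_tau_floor(self):
        img = self._image(np.ones((2, 2)))
        with pytest.raises(PhysicsError):
            to_ground_brightness(img, AtmosphericState(5e-4, 0.0, 0.0))


class TestEmissivityFromNdvi:
    def test_endpoint_values(self):
        eps, _ = emissivity_from_ndvi(np.array([0.1, 0.7]))
        assert eps[0] == 0.95
        assert eps[1] == 0.985

    def test_midpoint_hand_value(self):
        eps, pv = emissivity_from_ndvi(np.array([0.35]))
        assert pv[0] == pytest.approx(0.5)
        assert eps[0] == pytest.approx(0.9675)

    def test_continuity_at_both_thresholds(self):
        m = EmissivityModel()
        h = 1e-9
        for thr in (m.ndvi_soil, m.ndvi_veg):
            left, _ = emissivity_from_ndvi(np.array([thr - h]), m)
            right, _ = emissivity_from_ndvi(np.array([thr + h]), m)
            at, _ = emissivity_from_ndvi(np.array([thr]), m)
            assert abs(left[0] - at[0]) < 1e-9
            assert abs(right[0] - at[0]) < 1e-9

    @given(st.floats(min_value=-1.0, max_value=1.0))
    def test_bounds_and_monotonicity(self, ndvi_val):
        m = EmissivityModel()
        eps, pv = emissivity_from_ndvi(np.array([ndvi_val]), m)
        assert m.eps_soil <= eps[0] <= m.eps_veg
        assert 0.0 <= pv[0] <= 1.0

    def test_invalid_model_rejected(self):
        with pytest.raises(PhysicsError):
            EmissivityModel(ndvi_soil=0.6, ndvi_veg=0.5)


class TestResampleNdviToThermal:
    def test_identity_and_constant(self):
        g = Grid(0, 0, 1.0, 4, 4)
        vals = np.random.default_rng(0).uniform(0, 1, g.shape)
        m = IndexMap(name="NDVI", values=vals, grid=g)
        assert np.array_equal(resample_ndvi_to_thermal(m, g).values, vals)
        const = IndexMap(name="NDVI", values=np.full((4, 4), 0.3), grid=g)
        coarse = Grid(0, 0, 1.4, 2, 2)
        assert np.allclose(resample_ndvi_to_thermal(const, coarse).values, 0.3)

    def test_hand_resolved_nearest_assignment(self):
        # 2x2 fine grid (centers 0.5/1.5), one coarse pixel centered at 0.7
        fine = Grid(0, 0, 1.0, 2, 2)
        coarse = Grid(0, 0, 1.4, 1, 1)  # center (0.7, y1-0.7=0.7)
        vals = np.array([[1.0, 2.0], [3.0, 4.0]])
        m = IndexMap(name="NDVI", values=vals, grid=fine)
        out = resample_ndvi_to_thermal(m, coarse)
        # nearest fine center to (0.7, 0.7) is (0.5, 0.5) = row 1, col 0
        assert out.values[0, 0] == 3.0


class TestRetrieveLst:
    def test_unit_emissivity_identity_atmosphere(self, band):
        g = Grid(0, 0, 1.4, 3, 3)
        temps = np.linspace(290, 310, 9).reshape(3, 3)
        img = ThermalImage(values=np.asarray(band.radiance(temps)), grid=g)
        tmap = retrieve_lst(img, AtmosphericState(1.0, 0.0, 0.0), np.ones((3, 3)), band)
        assert np.allclose(tmap.values, temps, atol=1e-4)

    def test_noise_free_inverse_of_forward(self, band):
        g = Grid(0, 0, 1.4, 4, 4)
        rng = np.random.default_rng(5)
        temps = rng.uniform(290, 320, g.shape)
        eps = rng.uniform(0.95, 0.985, g.shape)
        atm = AtmosphericState(0.92, 5.0, 0.8)
        ground = eps * np.asarray(band.radiance(temps)) + (1 - eps) * atm.l_down
        img = ThermalImage(values=atm.tau * ground + atm.l_up, grid=g)
        tmap = retrieve_lst(img, atm, eps, band)
        assert np.nanmax(np.abs(tmap.values - temps)) < 0.01

    def test_nonpositive_emissivity_rejected(self, band):
        g = Grid(0, 0, 1.4, 2, 2)
        img = ThermalImage(values=np.full((2, 2), 9.0), grid=g)
        with pytest.raises(PhysicsError):
            retrieve_lst(img, AtmosphericState(1.0, 0.0, 0.0), np.zeros((2, 2)), band)
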