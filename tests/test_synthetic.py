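import numpy as np
import pytest

from prairiesense.layout import LayoutConfig, make_layout
from prairiesense.survey import diversity_metrics
from prairiesense.synthetic import (
    LatentFieldConfig,
    SceneConfig,
    SensorModel,
    SpeciesPool,
    SurfaceConfig,
    forward_thermal,
    forward_vnir,
    green_endmember,
    litter_endmember,
    make_scene_truth,
    sample_cover_tables,
    simulate_scene,
    soil_endmember,
    water_absorption,
)

ONE_BLOCK = LayoutConfig(n_blocks=1, extent=(320.0, 120.0))


def small_config(**surface_kwargs):
    return SceneConfig(
        layout=ONE_BLOCK,
        sensor=SensorModel(vnir_band_spacing_nm=9.2, vnir_gsd=2.0, thermal_gsd=2.8),
        surface=SurfaceConfig(**surface_kwargs),
    )


class TestSceneTruth:
    def test_cover_fractions_sum_to_one(self):
        truth = make_scene_truth(make_layout(ONE_BLOCK, 0), small_config(), seed=0)
        total = truth.cover_green + truth.cover_litter + truth.cover_soil
        off_tarp = truth.tarp_mask < 0
        assert np.allclose(total[off_tarp], 1.0, atol=1e-9)
        for f in (truth.cover_green, truth.cover_litter, truth.cover_soil):
            assert f.min() >= 0 and f.max() <= 1

    def test_reflectance_within_unit_interval(self):
        truth = make_scene_truth(make_layout(ONE_BLOCK, 0), small_config(), seed=0)
        assert truth.reflectance.values.min() >= 0
        assert truth.reflectance.values.max() <= 1

    def test_temperature_within_bounds(self):
        truth = make_scene_truth(make_layout(ONE_BLOCK, 0), small_config(), seed=0)
        assert truth.true_temperature.min() > 280
        assert truth.true_temperature.max() < 340

    def test_pure_green_pixel_equals_endmember(self):
        # a pixel with full green cover and water w mixes only the green
        # endmember with its water absorption
        wl = SensorModel().band_centers()
        em = green_endmember(wl) * (1 - 0.5 * water_absorption(wl) / 1.0)
        # mixture formula: green*(base) - green*water*base*absorption
        mix = 1.0 * green_endmember(wl) - 1.0 * 0.5 * (
            green_endmember(wl) * water_absorption(wl)
        )
        assert np.allclose(mix, em)

    def test_null_effects_give_flat_expected_temperature(self):
        cfg = small_config(t_green_k=0.0, t_water_k=0.0, t_noise_k=0.0)
        truth = make_scene_truth(make_layout(ONE_BLOCK, 0), cfg, seed=0)
        off_tarp = truth.tarp_mask < 0
        assert np.allclose(
            truth.true_temperature[off_tarp], cfg.surface.t_base_k, atol=1e-9
        )

    def test_temperature_anticorrelated_with_green_cover(self):
        truth = make_scene_truth(make_layout(ONE_BLOCK, 0), small_config(), seed=3)
        off_tarp = truth.tarp_mask < 0
        r = np.corrcoef(
            truth.cover_green[off_tarp].ravel(),
            truth.true_temperature[off_tarp].ravel(),
        )[0, 1]
        assert r < -0.5

    def test_deterministic_for_seed(self):
        layout = make_layout(ONE_BLOCK, 0)
        a = make_scene_truth(layout, small_config(), seed=9)
        b = make_scene_truth(layout, small_config(), seed=9)
        assert np.array_equal(a.reflectance.values, b.reflectance.values)
        assert np.array_equal(a.true_temperature, b.true_temperature)

    def test_endmember_ordering_supports_indices(self):
        wl = np.arange(400.0, 1000.1, 2.3)

        def toy_ndvi(spec):
            r = spec[np.argmin(np.abs(wl - 680))]
            n = spec[np.argmin(np.abs(wl - 800))]
            return (n - r) / (n + r)

        assert toy_ndvi(green_endmember(wl)) > 0.5
        assert toy_ndvi(soil_endmember(wl)) < 0.2
        assert toy_ndvi(litter_endmember(wl)) < 0.2


class TestCoverTables:
    def test_dominance_limit_shannon_near_zero(self):
        pool = SpeciesPool()
        layout = make_layout(ONE_BLOCK, 0)
        truth = make_scene_truth(
            layout,
            SceneConfig(
                layout=ONE_BLOCK,
                sensor=SensorModel(vnir_band_spacing_nm=9.2, vnir_gsd=2.0,
                                   thermal_gsd=2.8),
                latent=LatentFieldConfig(
                    seeding_mean=(0.0, 0.0, 0.0), burn_bonus=0.0,
                    block_sd=0.0, plot_sd=0.0, spatial_sd=0.0,
                ),
            ),
            seed=0,
        )
        table = sample_cover_tables(layout, truth, pool, seed=0)
        div = diversity_metrics(table, pool.functional_map())
        # latent 0 everywhere: brome-dominated, low diversity
        assert div["shannon_species"].mean() < 0.8

    def test_total_cover_conservation(self, compact_bundle):
        table = compact_bundle.cover_table
        veg = table[~table["species"].isin(("litter", "bare_soil"))]
        for _, grp in veg.groupby(["plot_id", "location_id"]):
            assert grp["percent_cover"].sum() <= 100 + 1e-9

    def test_burn_lowers_litter_in_expectation(self):
        pool = SpeciesPool()
        layout = make_layout(LayoutConfig(n_blocks=2, extent=(620.0, 120.0)), 0)
        cfg = SceneConfig(
            layout=LayoutConfig(n_blocks=2, extent=(620.0, 120.0)),
            sensor=SensorModel(vnir_band_spacing_nm=9.2, vnir_gsd=2.0,
                               thermal_gsd=2.8),
        )
        burn_means, hay_means = [], []
        for seed in range(200):
            truth = make_scene_truth(layout, cfg, seed=seed)
            table = sample_cover_tables(layout, truth, pool, seed=seed)
            litter = table[table["species"] == "litter"]
            burn_means.append(
                litter.loc[litter["management"] == "burn", "percent_cover"].mean()
            )
            hay_means.append(
                litter.loc[litter["management"] == "hay", "percent_cover"].mean()
            )
        assert np.mean(burn_means) < np.mean(hay_means)

    def test_seeding_raises_richness_and_c4_forb_share(self, compact_bundle):
        pool = SpeciesPool()
        div = diversity_metrics(compact_bundle.cover_table, pool.functional_map())
        div = div.merge(compact_bundle.layout.frame(), on="plot_id")
        by_seed = div.groupby("seeding")[["richness", "C4_share", "forb_share"]].mean()
        assert by_seed.loc["high", "richness"] > by_seed.loc["control", "richness"]
        assert by_seed.loc["high", "C4_share"] > by_seed.loc["control", "C4_share"]
        assert by_seed.loc["high", "forb_share"] > by_seed.loc["control", "forb_share"]

    def test_burning_shifts_ground_cover(self, compact_bundle):
        pool = SpeciesPool()
        div = diversity_metrics(compact_bundle.cover_table, pool.functional_map())
        div = div.merge(compact_bundle.layout.frame(), on="plot_id")
        by_mgmt = div.groupby("management")[
            ["litter_cover", "bare_soil_cover", "C3_share"]
        ].mean()
        assert by_mgmt.loc["burn", "litter_cover"] < by_mgmt.loc["hay", "litter_cover"]
        assert (
            by_mgmt.loc["burn", "bare_soil_cover"]
            > by_mgmt.loc["hay", "bare_soil_cover"]
        )
        assert by_mgmt.loc["burn", "C3_share"] < by_mgmt.loc["hay", "C3_share"]


class TestForwardModels:
    def test_vnir_identity_forward(self):
        from prairiesense.synthetic import AtmosphereConfig

        cfg = SceneConfig(
            layout=ONE_BLOCK,
            sensor=SensorModel(vnir_band_spacing_nm=9.2, vnir_gsd=2.0,
                               thermal_gsd=2.8, vnir_noise=0.0),
            atmosphere=AtmosphereConfig(
                vnir_gain_400=1.0, vnir_gain_1000=1.0, vnir_offset_400=0.0
            ),
        )
        truth = make_scene_truth(make_layout(ONE_BLOCK, 0), cfg, seed=0)
        cube, _ = forward_vnir(truth, cfg, seed=0, noise=0.0)
        assert np.allclose(cube.values, truth.reflectance.values, atol=1e-6)

    def test_empirical_line_recovers_simulated_gains(self, clean_bundle):
        from prairiesense.vnir import EmpiricalLineCalibrator

        cfg = clean_bundle.config
        wl = clean_bundle.vnir_cube.wavelengths
        model = EmpiricalLineCalibrator().fit(
            np.stack([t.reflectance_spectrum for t in clean_bundle.tarps]),
            np.stack([t.at_sensor_radiance_vnir for t in clean_bundle.tarps]),
        )
        assert np.allclose(model.gain_, cfg.atmosphere.vnir_gain(wl), rtol=1e-9)
        assert np.allclose(
            model.offset_, cfg.atmosphere.vnir_offset(wl), rtol=1e-9, atol=1e-12
        )

    def test_wbi_monotone_in_water_content(self):
        wl = np.arange(400.0, 1000.1, 2.3)
        i900 = np.argmin(np.abs(wl - 900))
        i970 = np.argmin(np.abs(wl - 970))
        wbis = []
        for w in (0.0, 0.3, 0.6, 0.9):
            spec = green_endmember(wl) - w * green_endmember(wl) * water_absorption(wl)
            wbis.append(spec[i900] / spec[i970])
        assert np.all(np.diff(wbis) > 0)

    def test_thermal_noise_free_determinism(self, clean_bundle):
        cfg = clean_bundle.config
        again = forward_thermal(clean_bundle.truth, cfg, seed=7, noise_k=0.0)
        assert np.array_equal(again.image.values, clean_bundle.thermal.image.values)

    def test_simulate_scene_bundles_are_consistent(self, compact_bundle):
        b = compact_bundle
        assert len(b.survey) == 15 * len(b.layout.plots)
        assert b.vnir_cube.grid.shape == b.truth.grid.shape
        assert b.thermal.image.grid.gsd == pytest.approx(2.8)
        assert len(b.tarps) == 3
        assert all(t.at_sensor_radiance_thermal is not None for t in b.tarps)
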