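"""Synthetic-world generators: determinism, closed forms, and the
elevation-band oracle that grounds the projection stage."""

import numpy as np
import pytest

from montrange.dispersal import SpeciesTraits
from montrange.grid import build_grid
from montrange.world import (
    CLIMATE_LAYERS,
    SOIL_LAYERS,
    InfeasibleSampleError,
    gaussian_suitability,
    generate_climate,
    generate_future_ensemble,
    generate_landuse,
    generate_terrain,
    simulate_species,
)

HERB = SpeciesTraits(growth_form="herb", dispersal_syndromes=frozenset({"animal"}))


class TestTerrain:
    def test_flat_world_without_ridges(self, tiny_grid):
        t = generate_terrain(tiny_grid, n_ridges=0, noise_sd=0.0, base_m=200.0,
                             mountain_elev_cut_m=1000.0, seed=0)
        assert (t.dem == 200.0).all()
        assert t.mountain_polygons == []

    def test_same_seed_bit_identical(self, tiny_grid):
        a = generate_terrain(tiny_grid, seed=5)
        b = generate_terrain(tiny_grid, seed=5)
        assert (a.dem == b.dem).all()

    def test_elevation_bound_over_many_seeds(self, tiny_grid):
        # base + n_ridges bumps of at most `amplitude` + smoothed noise
        # bounded by 6 sd: an upper envelope for any seed
        for seed in range(100):
            t = generate_terrain(tiny_grid, n_ridges=3, amplitude_m=2000.0,
                                 base_m=200.0, noise_sd=50.0, seed=seed)
            assert t.dem.max() <= 200.0 + 3 * 2000.0 + 6 * 50.0
            assert t.dem.min() >= 0.0

    def test_mountain_polygons_cover_high_cells(self, tiny_grid):
        t = generate_terrain(tiny_grid, n_ridges=2, amplitude_m=3000.0,
                             noise_sd=0.0, mountain_elev_cut_m=1500.0, seed=2)
        assert (t.dem >= 1500.0).any()
        assert len(t.mountain_polygons) >= 1


class TestClimate:
    def test_sea_level_temperature_at_reference_latitude(self):
        grid = build_grid(0, 1, -1, 1, 0.1)
        t = generate_terrain(grid, n_ridges=0, noise_sd=0.0, base_m=0.0, seed=0)
        env = generate_climate(t, sea_level_temp_C=26.0, lat_gradient_C_per_deg=0.5,
                               noise_sd=0.0, seed=0)
        mid_row = grid.n_rows // 2
        # the two rows straddling the reference latitude sit 0.05 deg away
        assert env.layers["bio1"][mid_row, 0] == pytest.approx(26.0 - 0.5 * 0.05)

    def test_lapse_rate_lowers_bio1(self, tiny_grid):
        t = generate_terrain(tiny_grid, n_ridges=0, noise_sd=0.0, base_m=1000.0, seed=0)
        env = generate_climate(t, sea_level_temp_C=26.0, lapse_C_per_km=6.5,
                               lat_gradient_C_per_deg=0.0, noise_sd=0.0, seed=0)
        np.testing.assert_allclose(env.layers["bio1"], 26.0 - 6.5)

    def test_bio1_monotone_in_elevation_without_noise(self, noise_free_world):
        terrain, env = noise_free_world
        row = terrain.dem.shape[0] // 2
        dem_row = terrain.dem[row]
        bio1_row = env.layers["bio1"][row]
        order = np.argsort(dem_row)
        diffs = np.diff(bio1_row[order])
        assert (diffs <= 1e-9).all()

    def test_layer_inventory(self, noisy_world):
        _, env = noisy_world
        assert set(CLIMATE_LAYERS) <= set(env.names)
        assert set(SOIL_LAYERS) <= set(env.names)
        assert "dem" in env.names
        assert len(env.names) == 13 + 9 + 1


class TestFutureEnsemble:
    def test_exact_warming_with_zero_spread(self, noise_free_world):
        _, env = noise_free_world
        ens = generate_future_ensemble(env, "SSPx", delta_T_C=2.0, precip_scale=1.0,
                                       n_gcm=5, gcm_spread_sd=0.0, precip_member_sd=0.0, seed=0)
        assert len(ens.members) == 5
        for m in ens.members:
            np.testing.assert_allclose(m.layers["bio1"] - env.layers["bio1"], 2.0)
            np.testing.assert_allclose(m.layers["bio12"], env.layers["bio12"])
            np.testing.assert_array_equal(m.layers["dem"], env.layers["dem"])

    def test_same_seed_identical_ensemble(self, noisy_world):
        _, env = noisy_world
        a = generate_future_ensemble(env, "S", 3.0, 0.9, n_gcm=3, seed=11)
        b = generate_future_ensemble(env, "S", 3.0, 0.9, n_gcm=3, seed=11)
        for ma, mb in zip(a.members, b.members):
            assert (ma.layers["bio1"] == mb.layers["bio1"]).all()


class TestLandUse:
    def test_fractions_sum_to_one(self, noisy_world):
        terrain, _ = noisy_world
        lu = generate_landuse(terrain, "base", crop_pressure=0.0, seed=4)
        np.testing.assert_allclose(lu.fractions.sum(axis=0), 1.0, atol=1e-6)

    def test_zero_pressure_scenario_equals_baseline(self, noisy_world):
        terrain, _ = noisy_world
        base = generate_landuse(terrain, "base", crop_pressure=0.0, seed=4)
        scen = generate_landuse(terrain, "SSP9", crop_pressure=0.0, seed=4)
        np.testing.assert_array_equal(base.fractions, scen.fractions)

    def test_crop_pressure_increases_crop_dominance(self, noisy_world):
        from montrange.projection import dominant_class
        from montrange.world import EXCLUDED_LANDUSE_CLASSES

        terrain, _ = noisy_world
        wins = 0
        for seed in range(20):
            base = generate_landuse(terrain, "b", crop_pressure=0.0, seed=seed)
            press = generate_landuse(terrain, "b", crop_pressure=4.0, seed=seed)
            crop_idx = [base.class_names.index(c) for c in EXCLUDED_LANDUSE_CLASSES]
            n_base = np.isin(dominant_class(base), crop_idx).sum()
            n_press = np.isin(dominant_class(press), crop_idx).sum()
            wins += n_press > n_base
        assert wins == 20

    def test_missing_excluded_class_rejected(self, noisy_world):
        terrain, _ = noisy_world
        with pytest.raises(ValueError, match="excluded"):
            generate_landuse(terrain, "b", class_names=["forest", "grassland", "corn"], seed=0)


class TestVirtualSpecies:
    def test_suitability_peaks_at_niche_center(self):
        s = gaussian_suitability(np.array([15.0]), np.array([1000.0]),
                                 niche_center=(15.0, 1000.0), niche_width=(1.0, 200.0))
        assert s[0] == pytest.approx(1.0)

    def test_infinite_precip_width_ignores_precipitation(self):
        bio1 = np.array([14.0, 15.0])
        a = gaussian_suitability(bio1, np.array([0.0, 5000.0]), (15.0, 100.0), (1.0, np.inf))
        b = gaussian_suitability(bio1, np.array([900.0, 900.0]), (15.0, 100.0), (1.0, np.inf))
        np.testing.assert_allclose(a, b)

    def test_truth_range_is_exact_elevation_band(self, noise_free_world):
        # with no noise and a temperature-only niche the truth range is
        # exactly the band |sea_level_T - lapse*z/1000 - muT| <= sigma*sqrt(-2 ln tau)
        terrain, env = noise_free_world
        muT, sT, tau = 16.0, 1.0, 0.5
        vs, _ = simulate_species(env, "v", (muT, 0.0), (sT, np.inf), tau, HERB,
                                 n_presence=30, seed=0)
        half_width_C = sT * np.sqrt(-2.0 * np.log(tau))
        bio1 = 26.0 - 6.5 * terrain.dem / 1000.0
        expected = np.abs(bio1 - muT) <= half_width_C
        np.testing.assert_array_equal(vs.truth_range, expected)

    def test_warming_raises_band_limits_by_delta_over_lapse(self, noise_free_world):
        terrain, env = noise_free_world
        muT, sT, tau, dT, lapse = 16.0, 1.0, 0.5, 2.0, 6.5
        ens = generate_future_ensemble(env, "S", dT, 1.0, n_gcm=1,
                                       gcm_spread_sd=0.0, precip_member_sd=0.0, seed=0)
        suit_now = gaussian_suitability(env.layers["bio1"], env.layers["bio12"],
                                        (muT, 0.0), (sT, np.inf))
        suit_fut = gaussian_suitability(ens.members[0].layers["bio1"],
                                        ens.members[0].layers["bio12"],
                                        (muT, 0.0), (sT, np.inf))
        z_now = terrain.dem[suit_now >= tau]
        z_fut = terrain.dem[suit_fut >= tau]
        shift_km = dT / lapse
        assert z_fut.min() == pytest.approx(z_now.min() + shift_km * 1000.0, abs=40.0)

    def test_presence_sample_concentrates_at_niche_center(self, noisy_world):
        _, env = noisy_world
        errs = []
        for seed in range(50):
            _, occ = simulate_species(env, "v", (16.0, 1400.0), (0.5, 500.0), 0.05, HERB,
                                      n_presence=200, sampling_bias_exp=2.0, seed=seed)
            row, col = env.grid.points_to_cells(occ["decimalLongitude"].to_numpy(),
                                                occ["decimalLatitude"].to_numpy())
            errs.append(abs(env.layers["bio1"][row, col].mean() - 16.0))
        assert np.mean(errs) < 0.2

    def test_infeasible_sample_raises(self, noisy_world):
        _, env = noisy_world
        with pytest.raises(InfeasibleSampleError):
            simulate_species(env, "v", (16.0, 1400.0), (0.05, 5.0), 0.99, HERB,
                             n_presence=5000, seed=0)

    def test_records_fall_inside_truth_cells(self, noisy_world):
        _, env = noisy_world
        vs, occ = simulate_species(env, "v", (17.0, 1200.0), (1.5, 300.0), 0.3, HERB,
                                   n_presence=100, seed=9)
        row, col = env.grid.points_to_cells(occ["decimalLongitude"].to_numpy(),
                                            occ["decimalLatitude"].to_numpy())
        assert (row >= 0).all()
        assert vs.truth_range[row, col].all()
        assert (occ["year"] >= 1981).all()
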