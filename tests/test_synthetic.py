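import json

import numpy as np
import pytest
from scipy.stats import spearmanr

from disaggval.synthetic_data import (
    SimulationConfig,
    disc_kernel,
    gaussian_random_field,
    generate_scene,
    generate_survey,
    ivory_coast_like,
    proportional_allocation,
    read_scene,
    uganda_like,
    write_scene,
)


def small_config(**overrides):
    defaults = dict(seed=0, grid_nrows=50, grid_ncols=50, n_locations=20, n_regions=4)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"grid_nrows": 0},
            {"cell_size_m": -1},
            {"n_locations": 0},
            {"settlement_threshold": 1.5},
            {"intercrop_prob": -0.1},
            {"density_class_probs": (0.5, 0.5, 0.0, 0.0, 0.1)},
            {"density_class_probs": (1.0,)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            small_config(**kwargs)

    def test_unknown_keys_rejected_on_load(self):
        with pytest.raises(ValueError, match="unknown"):
            SimulationConfig.from_dict({"seed": 1, "bogus": 2})

    def test_country_presets(self):
        ci = ivory_coast_like()
        ug = uganda_like()
        assert (ci.n_locations, ci.n_regions) == (69, 9)
        assert (ug.n_locations, ug.n_regions) == (87, 4)


class TestGenerateScene:
    def test_settlement_threshold_one_gives_all_zeros(self):
        scene = generate_scene(small_config(settlement_threshold=1.0))
        assert scene.settlement_raster.values.sum() == 0

    def test_settlement_values_are_binary_and_layers_nonnegative(self):
        scene = generate_scene(small_config())
        assert set(np.unique(scene.settlement_raster.values)) <= {0.0, 1.0}
        for layer in (scene.population_raster, scene.production_raster, scene.harvest_raster):
            assert (layer.values[~layer.mask] >= 0).all()

    def test_no_displacement_no_noise_matches_proportional_allocation_oracle(self):
        scene = generate_scene(small_config(displacement_m=0.0, link_noise_sd=0.0))
        pop = scene.population_raster.values
        regions = scene.region_raster.values.astype(int)
        # brute-force proportional allocation: within each region, production
        # must be exactly proportional to population, preserving region totals
        for r in np.unique(regions):
            in_r = regions == r
            prod = scene.production_raster.values[in_r]
            expected = prod.sum() * pop[in_r] / pop[in_r].sum()
            np.testing.assert_allclose(prod, expected, rtol=1e-9)

    def test_oracle_allocation_function_agrees_with_brute_force(self):
        rng = np.random.default_rng(0)
        pop = rng.uniform(1, 10, (8, 8))
        regions = np.repeat([1, 2], 32).reshape(8, 8)
        totals = {1: 100.0, 2: 50.0}
        out = proportional_allocation(pop, regions, totals)
        for r, total in totals.items():
            cells = out[regions == r]
            np.testing.assert_allclose(cells.sum(), total, rtol=1e-12)
            np.testing.assert_allclose(
                cells, total * pop[regions == r] / pop[regions == r].sum(), rtol=1e-12
            )

    def test_same_seed_identical_different_seed_differs(self):
        s42a = generate_scene(small_config(seed=42))
        s42b = generate_scene(small_config(seed=42))
        s43 = generate_scene(small_config(seed=43))
        np.testing.assert_array_equal(
            s42a.production_raster.values, s42b.production_raster.values
        )
        assert (s42a.production_raster.values != s43.production_raster.values).any()

    def test_locations_inside_extent_with_valid_region_labels(self):
        scene = generate_scene(small_config())
        for sv in scene.locations:
            assert scene.production_raster.contains(sv.longitude, sv.latitude)
            assert sv.region in {f"R{i}" for i in range(1, 5)}

    def test_harvest_no_greater_than_production(self):
        scene = generate_scene(small_config())
        assert (scene.harvest_raster.values <= scene.production_raster.values + 1e-12).all()


class TestGenerateSurvey:
    def test_zero_presence_probability_gives_empty_surveys(self):
        scene = generate_scene(small_config(presence_prob=0.0))
        assert all(len(sv.fields) == 0 for sv in scene.locations)
        assert all(sv.plants.n_plants == 0 for sv in scene.locations)

    def test_study_sized_cohort_has_expected_counts(self):
        scene = generate_scene(SimulationConfig(seed=5))  # 69 locations, 9 regions
        assert len(scene.locations) == 69
        assert len({sv.region for sv in scene.locations}) <= 9

    def test_noise_free_link_gives_perfect_rank_correlation(self):
        scene = generate_scene(small_config(link_noise_sd=0.0, presence_prob=1.0))
        truth = scene.truth
        rho = spearmanr(truth["true_proportion"], truth["allocation_value"]).statistic
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_presence_fraction_within_three_standard_errors(self):
        p = 0.75
        cfg = SimulationConfig(
            seed=2, grid_nrows=80, grid_ncols=80, n_locations=1000, n_regions=5, presence_prob=p
        )
        scene = generate_scene(cfg)
        frac = scene.truth["presence"].mean()
        se = np.sqrt(p * (1 - p) / 1000)
        assert abs(frac - p) < 3 * se

    def test_survey_regeneration_is_deterministic(self):
        cfg = small_config(seed=3)
        scene = generate_scene(cfg)
        again = generate_survey(scene, cfg)
        for a, b in zip(scene.locations, again):
            assert a.location_id == b.location_id
            assert len(a.fields) == len(b.fields)
            assert a.plants.n_plants == b.plants.n_plants


class TestScenePersistence:
    def test_round_trip_reproduces_rasters_and_config(self, tmp_path):
        scene = generate_scene(small_config(seed=4))
        write_scene(scene, tmp_path / "scene")
        back = read_scene(tmp_path / "scene")
        for name in scene.rasters:
            np.testing.assert_allclose(
                back.rasters[name].values, scene.rasters[name].values, atol=1e-9
            )
        assert back.config == scene.config
        assert len(back.locations) == len(scene.locations)
        for a, b in zip(scene.locations, back.locations):
            assert a.location_id == b.location_id
            assert a.region == b.region
            assert len(a.fields) == len(b.fields)
            assert a.plants.n_plants == b.plants.n_plants

    def test_manifest_lists_exactly_four_observable_rasters(self, tmp_path):
        scene = generate_scene(small_config(seed=4))
        manifest = write_scene(scene, tmp_path / "scene")
        assert len(manifest["rasters"]) == 4
        assert set(manifest["rasters"]) == {"production", "harvest", "population", "settlement"}

    def test_checksums_stable_across_writes(self, tmp_path):
        scene = generate_scene(small_config(seed=4))
        m1 = write_scene(scene, tmp_path / "a")
        m2 = write_scene(scene, tmp_path / "b")
        assert m1["files"] == m2["files"]

    def test_geojson_outputs_parse_with_polygon_fields(self, tmp_path):
        scene = generate_scene(small_config(seed=4, presence_prob=1.0))
        write_scene(scene, tmp_path / "scene")
        fields = json.loads((tmp_path / "scene" / "fields.geojson").read_text())
        assert fields["type"] == "FeatureCollection"
        assert fields["features"], "expected at least one field polygon"
        first = fields["features"][0]
        assert first["geometry"]["type"] == "Polygon"
        assert {"location_id", "management", "area_m2", "density_class"} <= set(
            first["properties"]
        )


def test_disc_kernel_identity_below_cell_size():
    assert disc_kernel(0.0, 1000.0).shape == (1, 1)
    k = disc_kernel(2000.0, 1000.0)
    assert k.shape == (5, 5)
    assert k.sum() == pytest.approx(1.0)


def test_random_field_is_standardized_and_correlated():
    rng = np.random.default_rng(0)
    f = gaussian_random_field(rng, 100, 100, 1000.0, 20_000.0)
    assert abs(f.mean()) < 0.5
    assert 0.5 < f.std() < 1.5
    # neighbouring cells are strongly correlated at range >> cell size
    r = np.corrcoef(f[:, :-1].ravel(), f[:, 1:].ravel())[0, 1]
    assert r > 0.8
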