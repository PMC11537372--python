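import numpy as np
import pytest

from disaggval.geo_extract import (
    BufferSpec,
    covariate_table,
    dissolved_cells,
    extract_points,
    zonal_summaries,
)
from disaggval.raster import RasterLayer
from disaggval.survey_metrics import LocationSurvey

from conftest import make_ramp_layer


def loc(x, y, loc_id="L1"):
    return LocationSurvey(loc_id, x, y)


def brute_force_zone(layer, x, y, distance_km):
    """Independent enumeration of in-circle, non-missing cell values."""
    vals = []
    for r in range(layer.nrows):
        for c in range(layer.ncols):
            cx = layer.x_origin + (c + 0.5) * layer.cell_size
            cy = layer.y_origin - (r + 0.5) * layer.cell_size
            if np.hypot(cx - x, cy - y) <= distance_km * 1000.0 and not layer.mask[r, c]:
                vals.append(layer.values[r, c])
    return np.array(vals)


class TestExtractPoints:
    def test_constant_raster_returns_constant(self):
        layer = RasterLayer(np.full((6, 6), 7.0), 0, 6000, 1000.0, name="c")
        res = extract_points(layer, [loc(500, 500, "A"), loc(5500, 5500, "B")])
        assert [r.value for r in res] == [7.0, 7.0]
        assert all(r.n_cells == 1 for r in res)

    def test_ramp_raster_cell_center_indexing(self, ramp_layer):
        # the center of cell (r, c) must return value r * ncols + c
        for r, c in [(0, 0), (2, 3), (9, 11)]:
            x = (c + 0.5) * 1000.0
            y = ramp_layer.y_origin - (r + 0.5) * 1000.0
            res = extract_points(ramp_layer, [loc(x, y)])
            assert res[0].value == r * 12 + c

    def test_point_outside_extent_is_missing_with_warning(self, ramp_layer):
        with pytest.warns(UserWarning, match="outside"):
            res = extract_points(ramp_layer, [loc(-1500.0, 500.0)])
        assert np.isnan(res[0].value)
        assert res[0].n_cells == 0

    def test_point_on_missing_cell_is_missing_with_warning(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        layer = RasterLayer(np.ones((4, 4)), 0, 4000, 1000.0, mask=mask)
        with pytest.warns(UserWarning, match="missing cell"):
            res = extract_points(layer, [loc(500, 3500)])
        assert np.isnan(res[0].value)


class TestZonalSummaries:
    def test_constant_raster_statistics(self):
        layer = RasterLayer(np.full((11, 11), 4.5), 0, 11_000, 1000.0, name="c")
        res = zonal_summaries(layer, [loc(5500, 5500)], BufferSpec(2))
        by_stat = {r.statistic: r.value for r in res}
        for stat in ("mean", "median", "min", "max", "q25", "q75"):
            assert by_stat[stat] == 4.5
        assert by_stat["sd"] == 0.0

    @pytest.mark.parametrize("distance_km", [2, 5, 10])
    def test_all_statistics_match_brute_force_enumeration(self, distance_km):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(25, 25))
        mask = rng.random((25, 25)) < 0.1
        layer = RasterLayer(values, 0, 25_000, 1000.0, mask=mask, name="r")
        x, y = 12_300.0, 11_700.0
        res = zonal_summaries(layer, [loc(x, y)], BufferSpec(distance_km))
        expected = brute_force_zone(layer, x, y, distance_km)
        by_stat = {r.statistic: r for r in res}
        assert by_stat["mean"].n_cells == expected.size
        assert by_stat["mean"].value == pytest.approx(expected.mean(), abs=1e-12)
        assert by_stat["median"].value == pytest.approx(np.median(expected), abs=1e-12)
        assert by_stat["sd"].value == pytest.approx(expected.std(ddof=1), abs=1e-12)
        assert by_stat["min"].value == expected.min()
        assert by_stat["max"].value == expected.max()
        assert by_stat["q25"].value == pytest.approx(np.quantile(expected, 0.25), abs=1e-12)
        assert by_stat["q75"].value == pytest.approx(np.quantile(expected, 0.75), abs=1e-12)

    def test_binary_layer_mean_is_settled_fraction(self):
        rng = np.random.default_rng(1)
        values = (rng.random((15, 15)) < 0.3).astype(float)
        layer = RasterLayer(values, 0, 15_000, 1000.0, name="settlement", binary=True)
        x, y = 7500.0, 7500.0
        res = zonal_summaries(layer, [loc(x, y)], BufferSpec(5), statistics=("mean",))
        expected = brute_force_zone(layer, x, y, 5)
        assert res[0].value == pytest.approx(expected.sum() / expected.size, abs=1e-12)

    def test_binary_layer_rejects_non_mean_statistics(self):
        layer = RasterLayer(np.zeros((5, 5)), 0, 5000, 1000.0, binary=True)
        with pytest.raises(ValueError, match="binary"):
            zonal_summaries(layer, [loc(2500, 2500)], BufferSpec(2))

    def test_quartile_ordering_and_mean_bounds(self, small_scene):
        res = zonal_summaries(
            small_scene.production_raster, small_scene.locations, BufferSpec(5)
        )
        by_loc = {}
        for r in res:
            by_loc.setdefault(r.location_id, {})[r.statistic] = r.value
        for stats in by_loc.values():
            assert stats["min"] <= stats["q25"] <= stats["median"] <= stats["q75"] <= stats["max"]
            assert stats["min"] <= stats["mean"] <= stats["max"]

    def test_results_invariant_to_location_order(self, small_scene):
        locs = small_scene.locations
        a = zonal_summaries(small_scene.production_raster, locs, BufferSpec(2))
        b = zonal_summaries(small_scene.production_raster, list(reversed(locs)), BufferSpec(2))
        key = lambda r: (r.location_id, r.statistic)
        assert sorted([(key(r), r.value) for r in a]) == sorted([(key(r), r.value) for r in b])

    def test_n_cells_non_decreasing_in_nested_distances(self, small_scene):
        counts = {}
        for d in (2, 5, 10):
            res = zonal_summaries(
                small_scene.production_raster, small_scene.locations, BufferSpec(d), ("mean",)
            )
            counts[d] = {r.location_id: r.n_cells for r in res}
        for loc_id in counts[2]:
            assert counts[2][loc_id] <= counts[5][loc_id] <= counts[10][loc_id]

    def test_empty_zone_warns_and_is_missing(self):
        mask = np.ones((30, 30), bool)
        mask[0, 0] = False
        layer = RasterLayer(np.ones((30, 30)), 0, 30_000, 1000.0, mask=mask)
        with pytest.warns(UserWarning, match="no eligible cells"):
            res = zonal_summaries(layer, [loc(25_000, 5_000)], BufferSpec(2), ("mean",))
        assert np.isnan(res[0].value)


class TestDissolvedCells:
    def test_disjoint_buffers_are_additive(self, ramp_layer):
        layer = make_ramp_layer(30, 30)
        a, b = loc(5000, 25_000, "A"), loc(25_000, 5000, "B")
        both = dissolved_cells(layer, [a, b], 2)
        only_a = dissolved_cells(layer, [a], 2)
        only_b = dissolved_cells(layer, [b], 2)
        assert len(both) == len(only_a) + len(only_b)

    def test_coincident_buffers_do_not_duplicate(self):
        layer = make_ramp_layer(30, 30)
        a, b = loc(15_000, 15_000, "A"), loc(15_000, 15_000, "B")
        assert len(dissolved_cells(layer, [a, b], 5)) == len(dissolved_cells(layer, [a], 5))

    def test_overlapping_buffers_match_brute_force_union(self):
        layer = make_ramp_layer(30, 30)
        locs = [loc(14_000, 15_000, "A"), loc(17_000, 15_500, "B")]
        result = dissolved_cells(layer, locs, 5)
        union = set()
        for lc in locs:
            vals = brute_force_zone(layer, lc.longitude, lc.latitude, 5)
            union.update(vals.tolist())  # ramp values are unique per cell
        assert set(result["value"]) == union
        assert len(result) == len(union)

    def test_empty_union_rejected(self):
        layer = make_ramp_layer(5, 5)
        with pytest.raises(ValueError, match="no eligible"):
            dissolved_cells(layer, [loc(1e6, 1e6)], 2)

    def test_bad_distance_rejected(self):
        layer = make_ramp_layer(5, 5)
        with pytest.raises(ValueError):
            dissolved_cells(layer, [loc(2500, 2500)], 0)


def test_covariate_table_shapes_one_row_per_location(small_scene):
    res = zonal_summaries(
        small_scene.production_raster, small_scene.locations, BufferSpec(2), ("mean", "sd")
    )
    res += extract_points(small_scene.production_raster, small_scene.locations)
    table = covariate_table(res)
    assert len(table) == len(small_scene.locations)
    assert {"production_0km_mean", "production_2km_mean", "production_2km_sd"} <= set(table.columns)


def test_buffer_spec_validation():
    with pytest.raises(ValueError):
        BufferSpec(7)
    with pytest.raises(ValueError):
        BufferSpec(0, mode="dissolved")
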