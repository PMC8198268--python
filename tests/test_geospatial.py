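"""Raster/vector operations against analytic surfaces and brute-force oracles."""

import math

import numpy as np
import pytest
from shapely.affinity import translate
from shapely.geometry import Point, box

from wrastic.core import DEFAULT_WEIGHTS, IndicatorScores, compute_wrastic
from wrastic.geospatial import (
    GeoConfig,
    ZeroValidCellsError,
    class_fraction,
    classify_surface,
    compute_aspect,
    compute_slope,
    evaluate_lake_geospatial,
    features_within,
    nearest_point_surface,
    per_pixel_index,
    rasterize,
    reclassify,
    zonal_stats,
)
from wrastic.rubrics import IRRIGATION_BINS
from wrastic.synthetic import SceneSpec, make_scene
from wrastic.vector import Feature, VectorLayer

from conftest import brute_force_zone_values, make_raster

CELL = 25.0


def plane(nrows, ncols, gx, gy, cell=CELL):
    """z = gx * x + gy * y at cell centres (x east, y north)."""
    x = (np.arange(ncols) + 0.5) * cell
    y = (nrows - np.arange(nrows)[:, None] - 0.5) * cell
    return make_raster(gx * x + gy * y + 0 * (x + y), cell=cell)


def horn_oracle(dem):
    """Independent scalar-loop Horn recomputation (slope deg, aspect deg)."""
    z, cell, nd = dem.values, dem.cell, dem.nodata
    nr, nc = z.shape
    slope = np.full_like(z, np.nan, dtype=float)
    aspect = np.full_like(z, np.nan, dtype=float)
    for r in range(1, nr - 1):
        for c in range(1, nc - 1):
            w = z[r - 1:r + 2, c - 1:c + 2]
            if np.any(w == nd):
                continue
            dzdx = ((w[0, 2] + 2 * w[1, 2] + w[2, 2])
                    - (w[0, 0] + 2 * w[1, 0] + w[2, 0])) / (8 * cell)
            dzds = ((w[2, 0] + 2 * w[2, 1] + w[2, 2])
                    - (w[0, 0] + 2 * w[0, 1] + w[0, 2])) / (8 * cell)
            dznorth = -dzds
            slope[r, c] = math.degrees(math.atan(math.hypot(dzdx, dznorth)))
            if dzdx == 0 and dznorth == 0:
                continue
            aspect[r, c] = math.degrees(math.atan2(-dzdx, -dznorth)) % 360
    return slope, aspect


class TestSlopeAspect:
    def test_constant_dem_is_flat(self):
        s = compute_slope(make_raster(np.full((8, 8), 42.0)))
        interior = s.values[1:-1, 1:-1]
        assert np.all(interior == 0)
        a = compute_aspect(make_raster(np.full((8, 8), 42.0)))
        assert not a.valid_mask().any()  # flat cells flagged nodata

    def test_unit_gradient_plane_is_45_degrees(self):
        s = compute_slope(plane(10, 10, gx=1.0, gy=0.0))
        np.testing.assert_allclose(s.values[1:-1, 1:-1], 45.0, atol=1e-9)

    def test_plane_dipping_east_has_aspect_90(self):
        a = compute_aspect(plane(10, 10, gx=-0.1, gy=0.0))  # z falls eastward
        np.testing.assert_allclose(a.values[1:-1, 1:-1], 90.0, atol=1e-9)

    def test_matches_scalar_loop_oracle_on_synthetic_hill(self, rng):
        x = (np.arange(24) + 0.5) * CELL
        y = (24 - np.arange(24)[:, None] - 0.5) * CELL
        hill = 40 * np.sin(x / 180) * np.cos(y / 150) + rng.normal(0, 0.5, (24, 24))
        dem = make_raster(hill)
        s_o, a_o = horn_oracle(dem)
        s = compute_slope(dem)
        a = compute_aspect(dem)
        np.testing.assert_allclose(s.values[1:-1, 1:-1], s_o[1:-1, 1:-1], atol=1e-6)
        np.testing.assert_allclose(a.values[1:-1, 1:-1], a_o[1:-1, 1:-1], atol=1e-6)

    def test_cone_aspect_points_radially_outward(self):
        n = 33
        cx = cy = n / 2 * CELL
        x = (np.arange(n) + 0.5) * CELL
        y = (n - np.arange(n)[:, None] - 0.5) * CELL
        r = np.hypot(x - cx, y - cy)
        dem = make_raster(1000 - 0.3 * r)
        a = compute_aspect(dem)
        for bearing in range(0, 360, 45):
            rad = math.radians(bearing)
            px = cx + 10 * CELL * math.sin(rad)
            py = cy + 10 * CELL * math.cos(rad)
            col = int(px / CELL)
            row = int(n - py / CELL)
            got = a.values[row, col]
            diff = abs(got - bearing) % 360
            assert min(diff, 360 - diff) < 3.0

    def test_nodata_propagates_through_window(self):
        vals = np.full((8, 8), 10.0)
        vals[4, 4] = -9999.0
        s = compute_slope(make_raster(vals))
        assert not s.valid_mask()[3:6, 3:6].any()

    def test_geographic_crs_rejected(self):
        dem = make_raster(np.zeros((4, 4)), crs="EPSG:4326")
        with pytest.raises(ValueError, match="reproject"):
            compute_slope(dem)


class TestReclassify:
    def test_category_map(self):
        tex = make_raster(np.array([[1.0, 2.0], [3.0, -9999.0]]))
        out = reclassify(tex, {1: 5, 2: 3, 3: 1})
        np.testing.assert_array_equal(out.values, [[5, 3], [1, -9999.0]])

    def test_all_nodata_stays_nodata(self):
        r = make_raster(np.full((3, 3), -9999.0))
        assert not reclassify(r, {0: 1}).valid_mask().any()

    def test_unmapped_category_raises_listing_values(self):
        r = make_raster(np.array([[1.0, 9.0]]))
        with pytest.raises(ValueError, match="9"):
            reclassify(r, {1: 2})
        out = reclassify(r, {1: 2}, default=0)
        np.testing.assert_array_equal(out.values, [[2.0, 0.0]])

    def test_bins_match_scalar_loop(self, rng):
        r = make_raster(rng.uniform(0, 100, (16, 16)))
        out = reclassify(r, IRRIGATION_BINS)
        expected = np.array([[IRRIGATION_BINS.grade(v) for v in row]
                             for row in r.values])
        np.testing.assert_array_equal(out.values, expected)


class TestZonal:
    def test_constant_raster(self):
        r = make_raster(np.full((10, 10), 7.0))
        zone = box(50, 50, 200, 200)
        assert zonal_stats(r, zone, "max") == 7.0
        assert zonal_stats(r, zone, "mean") == 7.0

    def test_two_valued_split(self):
        vals = np.full((10, 10), 1.0)
        vals[:3, :] = 2.0  # 30 of 100 cells
        r = make_raster(vals)
        pct = zonal_stats(r, box(0, 0, 250, 250), "class_percentages")
        assert pct == {1.0: 70.0, 2.0: 30.0}

    def test_matches_brute_force_on_irregular_polygon(self, rng, irregular_polygon):
        vals = rng.uniform(0, 50, (64, 64))
        vals[rng.random((64, 64)) < 0.05] = -9999.0
        r = make_raster(vals)
        oracle = brute_force_zone_values(r, irregular_polygon)
        assert zonal_stats(r, irregular_polygon, "max") == oracle.max()
        assert zonal_stats(r, irregular_polygon, "mean") == pytest.approx(oracle.mean())
        got_pct = zonal_stats(r, irregular_polygon, "percentiles")
        for p, v in got_pct.items():
            assert v == pytest.approx(np.percentile(oracle, p))
        pcts = zonal_stats(r.with_values(np.round(r.values / 10)), irregular_polygon,
                           "class_percentages")
        assert sum(pcts.values()) == pytest.approx(100.0, abs=1e-9)

    def test_mode_tie_breaks_to_lowest(self):
        vals = np.array([[1.0, 2.0], [2.0, 1.0]])
        r = make_raster(vals)
        assert zonal_stats(r, box(0, 0, 50, 50), "mode") == 1.0

    def test_zero_valid_cells_is_distinguishable(self):
        r = make_raster(np.zeros((4, 4)))
        with pytest.raises(ZeroValidCellsError):
            zonal_stats(r, box(1000, 1000, 1100, 1100), "max")

    def test_class_fraction(self, rng, irregular_polygon):
        codes = rng.integers(0, 5, (64, 64)).astype(float)
        r = make_raster(codes)
        oracle = brute_force_zone_values(r, irregular_polygon)
        want = 100.0 * np.isin(oracle, [1, 2]).sum() / oracle.size
        assert class_fraction(r, irregular_polygon, {1, 2}) == pytest.approx(want)
        full = make_raster(np.ones((8, 8)))
        assert class_fraction(full, box(0, 0, 200, 200), {1}) == 100.0
        assert class_fraction(full, box(0, 0, 200, 200), {9}) == 0.0


class TestVectorOps:
    def test_buffer_inclusion_threshold(self):
        lake = box(0, 0, 100, 100)
        pts = VectorLayer([
            Feature(Point(140, 50), {"id": 0}),   # 40 m away
            Feature(Point(160, 50), {"id": 1}),   # 60 m away
        ])
        hits = features_within(pts, lake, 50)
        assert [f.properties["id"] for f in hits] == [0]

    def test_matches_distance_oracle(self, rng):
        poly = box(200, 200, 700, 600)
        pts = VectorLayer([
            Feature(Point(x, y), {"id": i})
            for i, (x, y) in enumerate(rng.uniform(0, 1000, (60, 2)))
        ])
        got = {f.properties["id"] for f in features_within(pts, poly, 50)}
        want = {f.properties["id"] for f in pts if f.geometry.distance(poly) <= 50}
        assert got == want

    def test_crs_mismatch_rejected(self):
        pts = VectorLayer([Feature(Point(0, 0), {"population": 1})], crs="other")
        template = make_raster(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="crs"):
            nearest_point_surface(pts, "population", template)


class TestNearestPointSurface:
    def test_single_point_gives_constant(self):
        pts = VectorLayer([Feature(Point(50, 50), {"population": 9.0})])
        out = nearest_point_surface(pts, "population", make_raster(np.zeros((6, 6))))
        assert np.all(out.values == 9.0)

    def test_equidistant_tie_goes_to_lower_feature_id(self):
        template = make_raster(np.zeros((1, 2)), cell=100.0)
        # cell centres at x=50,150; points symmetric about x=100
        pts = VectorLayer([
            Feature(Point(100 - 30, 50), {"population": 1.0}),
            Feature(Point(100 + 30, 50), {"population": 2.0}),
        ])
        out = nearest_point_surface(pts, "population", template)
        mid = make_raster(np.zeros((1, 1)), cell=200.0)  # centre exactly at x=100
        tied = nearest_point_surface(pts, "population", mid)
        assert tied.values[0, 0] == 1.0
        assert list(out.values[0]) == [1.0, 2.0]

    def test_matches_exhaustive_search(self, rng):
        pts = VectorLayer([
            Feature(Point(x, y), {"population": float(i)})
            for i, (x, y) in enumerate(rng.uniform(0, 400, (10, 2)))
        ])
        template = make_raster(np.zeros((16, 16)))
        out = nearest_point_surface(pts, "population", template)
        for r in range(16):
            for c in range(16):
                x, y = (c + 0.5) * CELL, (16 - r - 0.5) * CELL
                d = [math.hypot(x - f.geometry.x, y - f.geometry.y) for f in pts]
                assert out.values[r, c] == float(int(np.argmin(d)))


class TestPerPixelIndex:
    def _stacks(self, vals_by_name, hazard_vals):
        grade = {k: make_raster(np.full((5, 5), float(v)))
                 for k, v in vals_by_name.items()}
        hazard = {k: make_raster(np.full((5, 5), float(v)))
                  for k, v in hazard_vals.items()}
        return grade, hazard

    def test_constant_stacks_match_tabular_engine(self):
        scores = IndicatorScores(W=3, R=5, A=5, a=2, S=1, T=3, I=3, C=4)
        grade, hazard = self._stacks(
            {k: getattr(scores, k) for k in "WRAaSTIC"},
            {"slope": 1, "aspect": 3, "permeability": 1},
        )
        out = per_pixel_index(grade, DEFAULT_WEIGHTS, hazard)
        expected = compute_wrastic(scores, DEFAULT_WEIGHTS)
        assert np.all(out.wrastic.values == expected)
        assert np.all(out.hi.values == 5)
        assert np.all(out.index.values == expected * 5)

    def test_nodata_in_any_input_propagates(self):
        grade, hazard = self._stacks(
            dict(W=1, R=1, A=1, a=1, S=1, T=1, I=1, C=1),
            {"slope": 1, "aspect": 3, "permeability": 1},
        )
        v = grade["A"].values.copy()
        v[2, 2] = grade["A"].nodata
        grade["A"] = grade["A"].with_values(v)
        out = per_pixel_index(grade, DEFAULT_WEIGHTS, hazard)
        assert out.index.values[2, 2] == out.index.nodata
        assert out.index.valid_mask().sum() == 24

    def test_random_stacks_match_scalar_loop(self, rng):
        grade = {k: make_raster(rng.integers(1, 5, (8, 8)).astype(float))
                 for k in "WRAaSTIC"}
        hazard = {"slope": make_raster(rng.choice([1, 3, 4, 5], (8, 8)).astype(float)),
                  "aspect": make_raster(rng.choice([1, 3, 5], (8, 8)).astype(float)),
                  "permeability": make_raster(rng.choice([1, 3, 5], (8, 8)).astype(float))}
        out = per_pixel_index(grade, DEFAULT_WEIGHTS, hazard)
        for r in range(8):
            for c in range(8):
                w = sum(grade[k].values[r, c] * getattr(DEFAULT_WEIGHTS, "w" + k)
                        for k in "WRAaSTIC")
                h = sum(hazard[k].values[r, c]
                        for k in ("slope", "aspect", "permeability"))
                assert out.wrastic.values[r, c] == w
                assert out.index.values[r, c] == w * h

    def test_missing_raster_named(self):
        grade, hazard = self._stacks(dict(W=1, R=1, A=1, a=1, S=1, T=1, I=1), {})
        with pytest.raises(ValueError, match="C"):
            per_pixel_index(grade, DEFAULT_WEIGHTS, hazard)


class TestRasterize:
    def test_polygon_attribute_burn(self):
        template = make_raster(np.zeros((8, 8)))
        soil = VectorLayer([
            Feature(box(0, 0, 100, 200), {"texture": "clay"}),
            Feature(box(100, 0, 150, 200), {"texture": "gravel"}),
        ])
        out = rasterize(soil, "texture", template, {"clay": 5, "sand": 3, "gravel": 1})
        assert out.values[0, 1] == 5.0 and out.values[0, 5] == 1.0
        assert out.values[0, 7] == out.nodata  # x>200 uncovered


class TestWorkflow:
    def test_missing_layer_is_named(self):
        scene = make_scene(SceneSpec(seed=3))
        scene.layers.soil = None
        with pytest.raises(ValueError, match="soil"):
            evaluate_lake_geospatial(scene.layers)

    def test_translation_invariance(self):
        spec = SceneSpec(seed=5, slope_grade=4, aspect_grade=5,
                         permeability_grade=3, pct_agricultural=30,
                         pct_irrigated=17, pct_vegetation=27,
                         transport_categories=("national_road",))
        scene = make_scene(spec)
        base = evaluate_lake_geospatial(scene.layers)

        dx, dy = 12345.0, -6789.0
        L = scene.layers
        L.dem = L.dem.translated(dx, dy)
        L.landcover = L.landcover.translated(dx, dy)
        L.watershed = translate(L.watershed, dx, dy)
        L.lake = Feature(translate(L.lake.geometry, dx, dy), L.lake.properties)
        for name in ("soil", "roads", "railways", "treatment_plants", "settlements",
                     "industrial", "exploitation", "tourist"):
            lyr = getattr(L, name)
            setattr(L, name, VectorLayer(
                [Feature(translate(f.geometry, dx, dy), f.properties) for f in lyr],
                lyr.crs))
        moved = evaluate_lake_geospatial(L)
        assert moved.scores == base.scores
        assert moved.hazards == base.hazards
        assert moved.result.state == base.result.state

    def test_class_percentages_sum_to_100(self):
        scene = make_scene(SceneSpec(seed=8, slope_grade=5, aspect_grade=5,
                                     permeability_grade=5, pct_vegetation=2,
                                     pct_agricultural=85, pct_irrigated=85))
        res = evaluate_lake_geospatial(scene.layers)
        assert sum(res.result.class_percentages.values()) == pytest.approx(100.0, abs=1e-9)

    def test_classify_surface_consistent_with_scalar_rule(self, rng):
        from wrastic.core import HazardType, classify

        w = make_raster(rng.integers(0, 120, (10, 10)).astype(float))
        hi = make_raster(rng.integers(3, 16, (10, 10)).astype(float))
        out = classify_surface(w, hi)
        from wrastic.core import DEFAULT_TYPE_RULE

        for r in range(10):
            for c in range(10):
                t = DEFAULT_TYPE_RULE.hazard_type(int(hi.values[r, c]))
                want = {"natural": 0, "semi_degraded": 1, "degraded": 2}[
                    classify(int(w.values[r, c]), t).value]
                assert out.values[r, c] == want
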