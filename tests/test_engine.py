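"""Unit and property tests for the grid-algebra primitives."""

import math

import numpy as np
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import LineString, Point, box

from stopovermap import (
    FactorLayer,
    Grid,
    ModifierLayer,
    apply_modifiers,
    buffer_carry_value,
    combine_mis,
    density_to_importance,
    focal_point_density,
    inverse_distance_decay,
    min_rect_northness,
    normalize01,
    quantile_classify,
    rasterize_valued_features,
    topographic_position,
    updraft_factor,
)
from stopovermap.engine import aspect_from_elevation, classify_aspect

from conftest import make_grid


class TestRasterize:
    def test_polyline_hits_expected_cells(self):
        tmpl = make_grid(np.zeros((10, 10)))
        # vertical line through the middle of column 3, all 10 rows
        line = LineString([(315.0, 900.0), (315.0, 0.0)])
        out = rasterize_valued_features([(line, 1.0)], tmpl)
        assert out.values[:, 3].tolist() == [1.0] * 10
        assert out.values.sum() == 10.0

    def test_max_combine_on_overlap(self):
        tmpl = make_grid(np.zeros((5, 5)))
        line = LineString([(0.0, 225.0), (450.0, 225.0)])
        out = rasterize_valued_features([(line, 0.5), (line, 1.0)], tmpl)
        assert out.values[2].tolist() == [1.0] * 5

    def test_empty_feature_set_gives_zero_grid(self):
        tmpl = make_grid(np.zeros((4, 4)))
        out = rasterize_valued_features([], tmpl)
        assert not out.values.any()

    def test_segments_match_cell_walk_oracle(self):
        """Three oblique segments on a 10x10 grid versus a brute-force
        per-cell box-intersection oracle."""
        tmpl = make_grid(np.zeros((10, 10)))
        segs = [
            LineString([(30.0, 870.0), (850.0, 100.0)]),
            LineString([(100.0, 100.0), (700.0, 820.0)]),
            LineString([(5.0, 450.0), (890.0, 470.0)]),
        ]
        out = rasterize_valued_features([(s, 1.0) for s in segs], tmpl)
        expect = np.zeros((10, 10))
        for r in range(10):
            for c in range(10):
                cell = box(c * 90.0, 900.0 - (r + 1) * 90.0, (c + 1) * 90.0, 900.0 - r * 90.0)
                if any(cell.intersects(s) for s in segs):
                    expect[r, c] = 1.0
        np.testing.assert_array_equal(out.values, expect)


class TestFocalDensity:
    def test_no_wetlands_all_zero(self):
        tmpl = make_grid(np.zeros((8, 8)))
        out = focal_point_density(np.empty((0, 2)), tmpl)
        assert not out.values.any()

    def test_157_points_in_disc_is_two_per_km2(self):
        rng = np.random.default_rng(1)
        tmpl = make_grid(np.zeros((115, 115)))
        cx, cy = 57 * 90.0 + 45.0, 115 * 90.0 - 57 * 90.0 - 45.0
        r = 5000.0 * np.sqrt(rng.uniform(0, 1, 157))
        th = rng.uniform(0, 2 * np.pi, 157)
        pts = np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])
        out = focal_point_density(pts, tmpl, radius=5000.0)
        assert out.values[57, 57] == pytest.approx(157 / (math.pi * 25.0))
        assert out.values[57, 57] == pytest.approx(2.0, abs=0.01)

    def test_single_point_density_within_radius(self):
        tmpl = make_grid(np.zeros((60, 60)))
        center = np.array([[30 * 90.0 + 45.0, 60 * 90.0 - 30 * 90.0 - 45.0]])
        out = focal_point_density(center, tmpl, radius=5000.0)
        one = 1.0 / (math.pi * 25.0)
        assert out.values[30, 30] == pytest.approx(one)
        assert out.values[0, 30] == pytest.approx(one)  # 2.7 km away
        far = out.values[0, 0]  # ~3.8 km away, still inside 5 km
        assert far == pytest.approx(one)

    def test_radius_below_cell_size_rejected(self):
        tmpl = make_grid(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="radius"):
            focal_point_density(np.zeros((1, 2)), tmpl, radius=50.0)


class TestDensityRamp:
    @pytest.mark.parametrize(
        "density,expected",
        [(2.0, 0.25), (28.0, 1.0), (15.0, 0.625), (1.9, 0.0), (50.0, 1.0), (0.0, 0.0)],
    )
    def test_ramp_values(self, density, expected):
        grid = make_grid([[density]])
        out = density_to_importance(grid)
        assert out.grid.values[0, 0] == pytest.approx(expected)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            density_to_importance(make_grid([[-1.0]]))


class TestInverseDistanceDecay:
    def test_source_keeps_value_and_cutoff(self):
        vals = np.zeros((13, 13))
        vals[6, 6] = 1.0
        out = inverse_distance_decay(make_grid(vals), max_dist=500.0)
        assert out.values[6, 6] == 1.0  # source unchanged at d = 0
        assert out.values[6, 8] == pytest.approx(0.25)  # (90/180)^2 at 180 m
        assert out.values[6, 1] == pytest.approx((90.0 / 450.0) ** 2)  # still inside
        assert out.values[6, 0] == 0.0  # 540 m is beyond the 500-m reach

    def test_decay_matches_brute_force(self):
        """EDT-based decay equals an all-pairs nearest-source computation."""
        rng = np.random.default_rng(3)
        vals = np.zeros((50, 50))
        src = rng.choice(2500, size=12, replace=False)
        vals.ravel()[src] = 1.0
        g = make_grid(vals)
        out = inverse_distance_decay(g, max_dist=500.0)
        rr, cc = np.nonzero(vals)
        expect = np.zeros((50, 50))
        for r in range(50):
            for c in range(50):
                if vals[r, c] > 0:
                    expect[r, c] = vals[r, c]
                    continue
                d = 90.0 * np.sqrt((rr - r) ** 2 + (cc - c) ** 2).min()
                if d <= 500.0:
                    expect[r, c] = min(1.0, (90.0 / d) ** 2)
        np.testing.assert_allclose(out.values, expect, atol=1e-12)

    def test_no_sources_gives_zero(self):
        out = inverse_distance_decay(make_grid(np.zeros((5, 5))))
        assert not out.values.any()


class TestBufferCarryValue:
    def test_value_carried_within_distance(self):
        tmpl = make_grid(np.zeros((30, 30)))
        wet = Point(15 * 90.0, 30 * 90.0 - 15 * 90.0).buffer(50.0)
        out = buffer_carry_value([(wet, 1.0)], 1000.0, tmpl)
        # a cell whose center is ~900 m away is inside the buffer
        assert out.values[15, 25] == 1.0
        # a cell center beyond 1100 m gets nothing
        assert out.values[15, 2] == 0.0

    def test_overlapping_buffers_take_max(self):
        tmpl = make_grid(np.zeros((20, 20)))
        a = Point(900.0, 900.0)
        b = Point(1000.0, 900.0)
        out = buffer_carry_value([(a, 0.5), (b, 1.0)], 800.0, tmpl)
        r, c = tmpl.cell_index(950.0, 900.0)
        assert out.values[r, c] == 1.0

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(7)
        tmpl = make_grid(np.zeros((50, 50)))
        feats = [
            (Point(rng.uniform(0, 4500), rng.uniform(0, 4500)), v)
            for v in (0.25, 0.5, 1.0)
        ] + [(LineString([(200.0, 200.0), (4000.0, 3500.0)]), 0.75)]
        out = buffer_carry_value(feats, 1000.0, tmpl)
        xs, ys = tmpl.cell_centers()
        expect = np.zeros((50, 50))
        for geom, v in feats:
            for r in range(50):
                for c in range(50):
                    if geom.distance(Point(xs[r, c], ys[r, c])) <= 1000.0:
                        expect[r, c] = max(expect[r, c], v)
        np.testing.assert_allclose(out.values, expect)


class TestNorthness:
    @pytest.mark.parametrize(
        "coords,expected",
        [
            ([(0, 0), (0, 1000)], 2.0),  # due north-south
            ([(0, 0), (1000, 0)], 1.0),  # due east-west
            ([(0, 0), (1000, 1000)], 1.5),  # azimuth 45 degrees
        ],
    )
    def test_reference_orientations(self, coords, expected):
        assert min_rect_northness(LineString(coords)) == pytest.approx(expected)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            min_rect_northness(LineString([(5.0, 5.0), (5.0, 5.0)]))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        st.floats(0.0, 179.9),
        st.floats(-1e5, 1e5),
        st.floats(-1e5, 1e5),
    )
    def test_translation_reversal_and_mirror_invariance(self, theta, dx, dy):
        az = math.radians(theta)
        a, b = (0.0, 0.0), (2000.0 * math.sin(az), 2000.0 * math.cos(az))
        base = min_rect_northness(LineString([a, b]))
        moved = min_rect_northness(LineString([(a[0] + dx, a[1] + dy), (b[0] + dx, b[1] + dy)]))
        reversed_ = min_rect_northness(LineString([b, a]))
        mirrored_az = math.radians(180.0 - theta)
        mirrored = min_rect_northness(
            LineString([(0, 0), (2000.0 * math.sin(mirrored_az), 2000.0 * math.cos(mirrored_az))])
        )
        assert moved == pytest.approx(base, abs=1e-6)
        assert reversed_ == pytest.approx(base, abs=1e-6)
        assert mirrored == pytest.approx(base, abs=1e-6)


class TestTopographicPosition:
    def test_constant_surface_all_zero(self):
        g = make_grid(np.full((40, 40), 1500.0))
        out = topographic_position(g, windows=(5, 10))
        assert not out.grid.values.any()

    def test_gaussian_ridge_crest_flagged(self):
        yy, xx = np.mgrid[0:60, 0:60]
        ridge = 2000.0 + 500.0 * np.exp(-0.5 * ((xx - 30) / 2.5) ** 2)
        out = topographic_position(make_grid(ridge), windows=(5, 10))
        assert out.grid.values[30, 30] == 1.0
        assert out.grid.values[:, 30].all()  # entire crest line
        assert out.grid.values[30, 5] == 0.0  # plain

    def test_valley_not_flagged(self):
        yy, xx = np.mgrid[0:60, 0:60]
        valley = 2000.0 - 500.0 * np.exp(-0.5 * ((xx - 30) / 2.5) ** 2)
        out = topographic_position(make_grid(valley), windows=(5, 10))
        assert out.grid.values[30, 30] == 0.0

    def test_window_larger_than_grid_rejected(self):
        with pytest.raises(ValueError):
            topographic_position(make_grid(np.zeros((10, 10))), windows=(20,))


class TestUpdraft:
    def _grids(self, aspect_deg, wind_cat):
        a = make_grid(np.full((2, 2), aspect_deg))
        w = make_grid(np.full((2, 2), float(wind_cat)))
        return a, w

    @pytest.mark.parametrize(
        "aspect_deg,wind,expected",
        [
            (0.0, 0, 1.0),     # aspect N, wind N
            (0.0, 1, 0.75),    # aspect N, wind NE
            (350.0, 0, 1.0),   # 350 degrees classifies as N
            (0.0, 4, 0.0),     # aspect N, wind S
            (0.0, 7, 0.75),    # circular adjacency across north
            (90.0, 2, 1.0),    # aspect E, wind E
        ],
    )
    def test_match_rules(self, aspect_deg, wind, expected):
        a, w = self._grids(aspect_deg, wind)
        out = updraft_factor(a, w)
        assert out.grid.values[0, 0] == expected

    def test_flat_cells_zero(self):
        a, w = self._grids(-1.0, 0)
        assert not updraft_factor(a, w).grid.values.any()

    def test_invalid_wind_category_rejected(self):
        a, w = self._grids(0.0, 9)
        with pytest.raises(ValueError):
            updraft_factor(a, w)

    def test_aspect_derivation_points_downhill(self):
        # elevation increasing to the west -> downslope faces east (90 deg)
        vals = np.tile(np.arange(20, 0, -1, dtype=float) * 10.0, (20, 1))
        aspect = aspect_from_elevation(make_grid(vals))
        assert classify_aspect(aspect)[10, 10] == 2  # east


class TestModelAlgebra:
    def test_unit_modifiers_leave_factor_unchanged(self):
        f = FactorLayer(make_grid(np.random.default_rng(0).uniform(0, 1, (5, 5))))
        m = ModifierLayer(make_grid(np.ones((5, 5))))
        out = apply_modifiers(f, [m, m])
        np.testing.assert_array_equal(out.values, f.grid.values)

    def test_zero_modifier_zeroes_everything(self):
        f = FactorLayer(make_grid(np.full((4, 4), 0.8)))
        z = ModifierLayer(make_grid(np.zeros((4, 4))))
        assert not apply_modifiers(f, [z]).values.any()

    def test_modifier_product_arithmetic(self):
        f = FactorLayer(make_grid(np.full((2, 2), 0.5)))
        m1 = ModifierLayer(make_grid(np.full((2, 2), 2.0)))
        m2 = ModifierLayer(make_grid(np.full((2, 2), 1.25)))
        out = apply_modifiers(f, [m1, m2])
        assert out.values[0, 0] == pytest.approx(1.25)

    def test_modifier_range_enforced(self):
        with pytest.raises(ValueError):
            ModifierLayer(make_grid(np.full((2, 2), 2.5)))
        with pytest.raises(ValueError):
            FactorLayer(make_grid(np.full((2, 2), 1.5)))

    def test_normalize01(self):
        np.testing.assert_array_equal(
            normalize01(make_grid(np.full((3, 3), 4.2))).values, np.ones((3, 3))
        )
        assert not normalize01(make_grid(np.zeros((3, 3)))).values.any()
        out = normalize01(make_grid([[0.0, 0.5, 2.0]]))
        np.testing.assert_allclose(out.values, [[0.0, 0.25, 1.0]])
        with pytest.raises(ValueError):
            normalize01(make_grid([[-0.1, 1.0]]))

    def test_combine_single_term_ignores_weight(self):
        term = make_grid(np.random.default_rng(1).uniform(0, 1, (4, 4)))
        term = normalize01(term)
        out = combine_mis([(term, 7.0)])
        np.testing.assert_allclose(out.values, term.values)

    def test_combine_two_terms_matches_hand_arithmetic(self):
        a = make_grid([[0.0, 0.5, 1.0], [0.25, 0.75, 0.5], [1.0, 0.0, 0.25]])
        b = make_grid([[1.0, 0.5, 0.0], [0.5, 0.25, 1.0], [0.0, 0.75, 0.5]])
        out = combine_mis([(a, 3.0), (b, 1.0)])
        raw = 3.0 * a.values + b.values
        np.testing.assert_allclose(out.values, raw / raw.max())

    def test_combine_invariant_to_weight_scaling(self):
        a = normalize01(make_grid(np.random.default_rng(2).uniform(0, 1, (5, 5))))
        b = normalize01(make_grid(np.random.default_rng(3).uniform(0, 1, (5, 5))))
        one = combine_mis([(a, 1.0), (b, 2.0)])
        scaled = combine_mis([(a, 10.0), (b, 20.0)])
        np.testing.assert_allclose(one.values, scaled.values)

    def test_combine_rejects_nonpositive_weight(self):
        a = make_grid(np.ones((2, 2)))
        with pytest.raises(ValueError):
            combine_mis([(a, 0.0)])


class TestQuantileClassify:
    def test_uniform_values_balanced_bins(self):
        g = make_grid(np.arange(1.0, 101.0).reshape(10, 10))
        qc = quantile_classify(g, k=5)
        counts = np.bincount(qc.classes.values.astype(int).ravel())[1:]
        assert counts.tolist() == [20, 20, 20, 20, 20]
        assert qc.k_effective == 5

    def test_zero_mass_merges_bins(self):
        vals = np.zeros(100)
        vals[70:] = np.arange(1.0, 31.0)
        qc = quantile_classify(make_grid(vals.reshape(10, 10)), k=5)
        assert qc.k_effective < 5
        assert np.all(qc.classes.values.ravel()[:70] == 1)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        g = make_grid(rng.uniform(0, 1, (12, 12)))
        base = quantile_classify(g, k=5).classes.values
        for transform in (np.exp, np.sqrt, lambda v: 3 * v + 2):
            same = quantile_classify(g.with_values(transform(g.values)), k=5).classes.values
            np.testing.assert_array_equal(base, same)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            quantile_classify(make_grid(np.ones((1, 3))), k=5)
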