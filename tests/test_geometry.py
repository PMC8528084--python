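import math

import numpy as np
import pytest
from shapely.geometry import Point
from shapely.ops import unary_union

from toxpimap import (
    ConfigurationError,
    CRSError,
    GlyphSpec,
    ValidationError,
    build_glyph,
    build_ring,
    build_wedge,
    slice_angles,
)
from toxpimap.crs import GRS80_A, AlbersEqualArea, get_crs


class TestSliceAngles:
    def test_equal_partition(self):
        angles = slice_angles([1, 1, 1, 1])
        assert angles == [(0, 90), (90, 180), (180, 270), (270, 360)]

    def test_proportional_widths(self):
        widths = [e - s for s, e in slice_angles([2, 1, 1])]
        assert widths == pytest.approx([180, 90, 90])

    def test_single_slice_spans_full_circle(self):
        assert slice_angles([7.3]) == [(0.0, 360.0)]

    def test_widths_sum_exactly_to_360(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            w = rng.uniform(0.01, 10, rng.integers(1, 20))
            angles = slice_angles(w, start_bearing=rng.uniform(0, 360))
            total = sum(e - s for s, e in angles)
            assert abs(total - 360.0) <= 1e-9
            # contiguity
            for (s1, e1), (s2, _) in zip(angles, angles[1:]):
                assert e1 == s2

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ConfigurationError):
            slice_angles([1, 0, 2])


class TestProjection:
    def test_round_trip_under_1e6_degrees(self):
        crs = get_crs("EPSG:5070")
        rng = np.random.default_rng(0)
        lat = rng.uniform(-85, 85, 200)
        lon = rng.uniform(-179, 179, 200)
        la, lo = crs.unproject(*crs.project(lat, lon))
        assert np.max(np.abs(la - lat)) < 1e-6
        assert np.max(np.abs(lo - lon)) < 1e-6

    def test_latitude_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            get_crs(5070).project(100.0, 0.0)

    def test_unknown_epsg_code_rejected(self):
        with pytest.raises(CRSError):
            get_crs(99999)

    def test_equator_degree_matches_ellipsoidal_arc(self):
        # oracle: along the equator the ellipsoidal arc of dL radians is
        # exactly a * dL (the equator is a circle of radius a)
        expected_m = GRS80_A * math.radians(1.0)
        crs = AlbersEqualArea(lat_1=0.0, lat_2=30.0, lat_0=0.0, lon_0=-0.5)
        x1, y1 = crs.project(0.0, -1.0)
        x2, y2 = crs.project(0.0, 0.0)
        assert math.hypot(x2 - x1, y2 - y1) == pytest.approx(expected_m, rel=1e-3)

    def test_degenerate_symmetric_parallels_rejected(self):
        with pytest.raises(CRSError, match="degenerate"):
            AlbersEqualArea(lat_1=-10.0, lat_2=10.0)


class TestBuildWedge:
    def test_full_circle_area_within_0p2_percent(self):
        r = 1000.0
        poly = build_wedge((0, 0), 0, 360, r, arc_step=5.0)
        # closed-form oracle: regular n-gon area = n/2 * r^2 * sin(2*pi/n)
        n = 72
        expected = 0.5 * n * r * r * math.sin(2 * math.pi / n)
        assert poly.area == pytest.approx(expected, rel=1e-12)
        assert abs(poly.area - math.pi * r * r) / (math.pi * r * r) < 0.002

    def test_first_arc_vertex_is_due_north(self):
        poly = build_wedge((10.0, 20.0), 0, 90, 5.0, arc_step=5.0)
        coords = list(poly.exterior.coords)
        assert coords[0] == (10.0, 20.0)  # center first
        assert coords[1] == pytest.approx((10.0, 25.0))

    def test_ring_closed_and_simple(self):
        poly = build_wedge((0, 0), 30, 110, 100.0, arc_step=5.0)
        coords = list(poly.exterior.coords)
        assert coords[0] == coords[-1]
        assert len(coords) >= 4
        assert poly.is_valid  # non-self-intersecting

    def test_zero_width_sector_rejected(self):
        with pytest.raises(ConfigurationError):
            build_wedge((0, 0), 45, 45, 100.0)

    def test_sector_area_converges_to_theta_half_r_squared(self):
        r, theta = 500.0, 72.0
        poly = build_wedge((0, 0), 0, theta, r, arc_step=0.25)
        assert poly.area == pytest.approx(math.radians(theta) / 2 * r * r, rel=1e-4)


class TestBuildRing:
    def test_vertex_count(self):
        ring = build_ring((0, 0), 100.0, arc_step=5.0)
        assert len(ring.exterior.coords) == 360 // 5 + 1

    def test_perimeter_within_0p15_percent(self):
        r = 1000.0
        ring = build_ring((0, 0), r, arc_step=5.0)
        # chord-length oracle: 72 chords of 2*r*sin(2.5 deg)
        expected = 72 * 2 * r * math.sin(math.radians(2.5))
        assert ring.exterior.length == pytest.approx(expected, rel=1e-12)
        assert abs(ring.exterior.length - 2 * math.pi * r) / (2 * math.pi * r) < 0.0015

    def test_ring_contains_every_wedge_vertex(self, tiny_results):
        spec = GlyphSpec(radius_max=1000.0)
        wedges = build_glyph(tiny_results, "b", (0.0, 0.0), spec)
        ring = build_ring((0.0, 0.0), 1000.0 * 1.001)  # tolerance for chords
        for w in wedges:
            for x, y in w.polygon.exterior.coords:
                assert ring.contains(Point(x, y)) or ring.touches(Point(x, y))


class TestBuildGlyph:
    def test_one_wedge_per_slice_with_attributes(self, tiny_results, tiny_model):
        spec = GlyphSpec(radius_max=2000.0)
        wedges = build_glyph(tiny_results, "a", (5.0, 7.0), spec)
        assert len(wedges) == len(tiny_model.slices)
        names = [w.attributes["slice"] for w in wedges]
        assert names == tiny_model.slice_names
        for w in wedges:
            assert w.attributes["record_id"] == "a"
            assert 0 <= w.attributes["slice_score"] <= 1
            assert w.attributes["color"].startswith("#")
            assert any(k.startswith("raw::") for k in w.attributes)

    def test_zero_score_slice_gets_radius_floor(self, tiny_results):
        spec = GlyphSpec(radius_max=1000.0, min_radius_fraction=0.01)
        # record "a" has scaled exposure score 0
        wedge = build_glyph(tiny_results, "a", (0.0, 0.0), spec)[0]
        assert wedge.attributes["slice_score"] == 0.0
        max_r = max(math.hypot(x, y) for x, y in wedge.polygon.exterior.coords)
        assert max_r == pytest.approx(10.0)

    def test_full_scores_tile_the_disc(self, tiny_model, tiny_results):
        import pandas as pd

        from toxpimap.scoring import ToxPiResults
        ids = tiny_results.slice_scores.index
        ones = ToxPiResults(
            model=tiny_model,
            slice_scores=tiny_results.slice_scores * 0 + 1.0,
            overall=tiny_results.overall * 0 + 1.0,
            lat=tiny_results.lat, lon=tiny_results.lon,
        )
        spec = GlyphSpec(radius_max=100.0)
        union = unary_union([w.polygon for w in build_glyph(ones, "a", (0, 0), spec)])
        disc = build_ring((0, 0), 100.0)
        assert union.area == pytest.approx(disc.area, rel=1e-9)

    def test_subset_recomputes_angles_over_subset_weights(self, tiny_results):
        spec = GlyphSpec(radius_max=100.0)
        wedges = build_glyph(
            tiny_results, "b", (0, 0), spec,
            slice_subset=["exposure", "protection"],
        )
        assert len(wedges) == 2
        # weights 2 and 1 -> widths 240 and 120, summing to 360
        fracs = [w.attributes["weight_fraction"] for w in wedges]
        assert fracs == pytest.approx([2 / 3, 1 / 3])

    def test_subset_unknown_slice_listed(self, tiny_results):
        with pytest.raises(ConfigurationError, match="ghost"):
            build_glyph(tiny_results, "a", (0, 0), GlyphSpec(),
                        slice_subset=["exposure", "ghost"])


class TestGlyphInvariants:
    def _random_glyphs(self, n_glyphs=50, seed=2):
        import pandas as pd

        from toxpimap import pvi_like_model, score
        from conftest import random_matrix
        rng = np.random.default_rng(seed)
        model = pvi_like_model()
        results = score(random_matrix(rng, model, n=n_glyphs), model)
        return results, rng

    def test_wedges_pairwise_interior_disjoint(self):
        results, rng = self._random_glyphs()
        spec = GlyphSpec(radius_max=1000.0)
        for rid in results.record_ids:
            wedges = [w.polygon for w in build_glyph(results, rid, (0, 0), spec)]
            for i in range(len(wedges)):
                for j in range(i + 1, len(wedges)):
                    inter = wedges[i].intersection(wedges[j])
                    assert inter.area < 1e-9

    def test_doubling_radius_quadruples_area(self, tiny_results):
        a1 = sum(w.polygon.area for w in
                 build_glyph(tiny_results, "b", (0, 0), GlyphSpec(radius_max=500.0)))
        a2 = sum(w.polygon.area for w in
                 build_glyph(tiny_results, "b", (0, 0), GlyphSpec(radius_max=1000.0)))
        assert a2 == pytest.approx(4 * a1, rel=1e-9)

    def test_full_glyph_centroid_at_projected_point(self, tiny_results):
        from toxpimap.scoring import ToxPiResults
        ones = ToxPiResults(
            model=tiny_results.model,
            slice_scores=tiny_results.slice_scores * 0 + 1.0,
            overall=tiny_results.overall * 0 + 1.0,
            lat=tiny_results.lat, lon=tiny_results.lon,
        )
        spec = GlyphSpec(radius_max=1000.0)
        cx, cy = 12345.0, -6789.0
        union = unary_union(
            [w.polygon for w in build_glyph(ones, "c", (cx, cy), spec)]
        )
        assert union.centroid.x == pytest.approx(cx, abs=1e-6 * 1000)
        assert union.centroid.y == pytest.approx(cy, abs=1e-6 * 1000)
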