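"""Inscribed-circle JSW: parallel plates, wedge oracle, invariances."""

import numpy as np
import pytest

from conftest import grid_inscribed_radius, random_convex_gap
from kneequant.geometry import build_framework
from kneequant.jsw import (clip_boundaries, inscribed_circle_at,
                           max_inscribed_on_axis, measure_jsw,
                           point_polyline_distance)
from kneequant.landmarks import LandmarkSet, canonicalize
from kneequant.phantom import PHANTOM_SUITE, generate_phantom


@pytest.fixture(scope="module")
def parallel_setup():
    p = PHANTOM_SUITE["parallel"]
    ls = generate_phantom(p)[1]
    return p, ls, build_framework(ls)


class TestPointPolylineDistance:
    def test_matches_sampling_oracle(self):
        from conftest import brute_force_point_polyline
        rng = np.random.default_rng(3)
        poly = np.cumsum(rng.uniform(-2, 3, size=(6, 2)), axis=0)
        for point in rng.uniform(-5, 10, size=(5, 2)):
            exact = float(point_polyline_distance(point, poly)[0])
            approx = brute_force_point_polyline(point, poly, n_samples=4001)
            assert exact == pytest.approx(approx, abs=1e-3)
            assert exact <= approx + 1e-12  # exact distance is never larger


class TestClipBoundaries:
    def test_clip_spans_exactly_the_band(self, parallel_setup):
        _p, ls, fw = parallel_setup
        for comp in ("medial", "lateral"):
            b = clip_boundaries(ls, fw, comp)
            lo, hi = b.band_interval
            for poly in (b.upper, b.lower):
                s = fw.tibial_station_of(poly)
                assert s.min() == pytest.approx(lo, abs=1e-9)
                assert s.max() == pytest.approx(hi, abs=1e-9)
            assert not b.extrapolated

    def test_clipped_points_lie_on_original_segments(self, parallel_setup):
        _p, ls, fw = parallel_setup
        from kneequant.landmarks import region_points
        orig = region_points(ls, "femur_lateral_condyle")
        b = clip_boundaries(ls, fw, "lateral")
        assert np.all(point_polyline_distance(b.upper, orig) < 1e-6)

    def test_band_beyond_polyline_sets_extrapolated_flag(self, parallel_setup):
        """Shrinking the annotated plateau forces terminal-segment extrapolation."""
        p, ls, fw = parallel_setup
        pts = ls.points.copy()
        # pull the outermost lateral plateau points (24, 25) inboard so the
        # annotated span no longer covers the band
        pts[23] = pts[21]
        pts[24] = pts[22]
        ls2 = LandmarkSet(pts, laterality="right")
        b = clip_boundaries(ls2, fw, "lateral")
        assert b.extrapolated


class TestInscribedCircle:
    def test_parallel_plates_radius_five(self, parallel_setup):
        p, ls, fw = parallel_setup
        boundary = clip_boundaries(ls, fw, "lateral")
        for s in fw.tibial_bands["lateral"].stations(5):
            c = inscribed_circle_at(boundary, fw, s)
            assert c.radius == pytest.approx(5.0, abs=1e-5)
            assert c.center[1] == pytest.approx(p.tibial_y - 5.0, abs=1e-5)

    def test_circle_touches_both_boundaries(self, parallel_setup):
        _p, ls, fw = parallel_setup
        for comp in ("medial", "lateral"):
            boundary = clip_boundaries(ls, fw, comp)
            for s in fw.tibial_bands[comp].stations(3):
                c = inscribed_circle_at(boundary, fw, s)
                d_up = float(point_polyline_distance(c.center, boundary.upper)[0])
                d_lo = float(point_polyline_distance(c.center, boundary.lower)[0])
                assert d_up >= c.radius - 1e-4
                assert d_lo >= c.radius - 1e-4
                assert min(d_up, d_lo) <= c.radius + 1e-3

    def test_zero_gap_gives_zero_radius(self):
        upper = np.array([[0.0, 100.0], [10.0, 100.0]])
        lower = np.array([[0.0, 100.0], [10.0, 100.0]])
        t, r, crossing = max_inscribed_on_axis([5.0, 100.0], [0.0, -1.0], upper, lower)
        assert r == 0.0 and not crossing

    def test_crossing_boundaries_flagged_never_negative(self):
        upper = np.array([[0.0, 105.0], [10.0, 105.0]])   # below the "lower" line
        lower = np.array([[0.0, 100.0], [10.0, 100.0]])
        t, r, crossing = max_inscribed_on_axis([5.0, 102.0], [0.0, -1.0], upper, lower)
        assert r == 0.0 and crossing

    def test_wedge_gap_matches_grid_oracle(self):
        """Linear wedge between plates: optimizer vs dense grid search."""
        theta = np.radians(3.0)
        upper = np.array([[0.0, 100.0 - 0.0], [40.0, 100.0 - 40.0 * np.tan(theta)]])
        lower = np.array([[0.0, 100.0], [40.0, 100.0]])
        for x0 in (8.0, 20.0, 33.0):
            gap = x0 * np.tan(theta)  # vertical separation at the station
            t, r, _ = max_inscribed_on_axis([x0, 100.0], [0.0, -1.0], upper, lower)
            r_grid = grid_inscribed_radius([x0, 100.0], [0.0, -1.0], upper, lower,
                                           0.0, gap, step=2e-4)
            assert r == pytest.approx(r_grid, abs=1e-3)

    def test_random_convex_gaps_match_grid_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            upper, lower = random_convex_gap(rng)
            x0 = rng.uniform(5.0, 35.0)
            y_lo = float(np.interp(x0, lower[:, 0], lower[:, 1]))
            y_up = float(np.interp(x0, upper[:, 0], upper[:, 1]))
            p0 = [x0, y_lo]
            t, r, _ = max_inscribed_on_axis(p0, [0.0, -1.0], upper, lower)
            r_grid = grid_inscribed_radius(p0, [0.0, -1.0], upper, lower,
                                           0.0, y_lo - y_up, step=5e-4)
            assert r == pytest.approx(r_grid, abs=1e-3)


class TestMeasureJSW:
    def test_parallel_fixture_two_millimetres(self, parallel_setup):
        p, ls, fw = parallel_setup
        res = measure_jsw(ls, fw, p.pixel_spacing)
        assert len(res.circles) == 30
        assert res.mean_medial_jsw == pytest.approx(2.0, abs=1e-4)
        assert res.mean_lateral_jsw == pytest.approx(2.0, abs=1e-4)
        assert res.minimal_jsw == pytest.approx(2.0, abs=1e-4)

    def test_minimal_jsw_is_global_minimum(self, parallel_setup):
        p = PHANTOM_SUITE["narrowed_lateral"]
        ls = generate_phantom(p)[1]
        fw = build_framework(ls)
        res = measure_jsw(ls, fw, p.pixel_spacing)
        diam = res.diameters_px() * p.pixel_spacing
        assert res.minimal_jsw == pytest.approx(diam.min())
        assert res.minimal_jsw <= min(res.mean_medial_jsw, res.mean_lateral_jsw)
        assert res.minimal_jsw_compartment == "lateral"

    def test_tilted_gap_minimum_at_narrow_corner(self):
        """With a uniformly converging gap the smallest circle sits at the
        station nearest the narrow corner."""
        p = PHANTOM_SUITE["narrowed_lateral"]
        ls = generate_phantom(p)[1]
        fw = build_framework(ls)
        res = measure_jsw(ls, fw, p.pixel_spacing)
        lat = [c for c in res.circles if c.compartment == "lateral"]
        smallest = min(lat, key=lambda c: c.diameter)
        assert smallest.station == pytest.approx(
            min(fw.tibial_bands["lateral"].stations(15)))

    def test_pixel_spacing_scales_mm_only(self, parallel_setup):
        _p, ls, fw = parallel_setup
        r1 = measure_jsw(ls, fw, 0.2)
        r2 = measure_jsw(ls, fw, 0.4)
        assert r2.mean_medial_jsw == pytest.approx(2 * r1.mean_medial_jsw)
        assert np.allclose(r1.diameters_px(), r2.diameters_px())

    def test_rigid_rotation_leaves_diameters_unchanged(self):
        p = PHANTOM_SUITE["tilted_femoral"]
        ls = generate_phantom(p)[1]
        fw = build_framework(ls)
        d0 = measure_jsw(ls, fw, p.pixel_spacing).diameters_px()
        theta = np.radians(5.0)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        center = np.array([250.0, 300.0])
        ls2 = LandmarkSet((ls.points - center) @ rot.T + center, laterality="right")
        fw2 = build_framework(ls2)
        d1 = measure_jsw(ls2, fw2, p.pixel_spacing).diameters_px()
        assert np.allclose(np.sort(d0), np.sort(d1), atol=1e-4)

    def test_enlarging_gap_never_shrinks_any_circle(self):
        """Translating the femoral side proximally widens every local JSW."""
        p = PHANTOM_SUITE["parallel"]
        ls = generate_phantom(p)[1]
        femoral = list(range(58, 99))  # all femoral indices
        d_prev = None
        for dy in (0.0, 3.0, 6.0):
            pts = ls.points.copy()
            pts[[i - 1 for i in femoral], 1] -= dy
            ls2 = LandmarkSet(pts, laterality="right")
            fw2 = build_framework(ls2)
            d = measure_jsw(ls2, fw2, p.pixel_spacing).diameters_px()
            if d_prev is not None:
                assert np.all(d >= d_prev - 1e-6)
            d_prev = d

    def test_crossing_stations_reported_in_warnings(self):
        p = PHANTOM_SUITE["parallel"]
        ls = generate_phantom(p)[1]
        pts = ls.points.copy()
        pts[[i - 1 for i in range(58, 99)], 1] += 12.0  # femur pushed past the tibia
        ls2 = LandmarkSet(pts, laterality="right")
        fw2 = build_framework(ls2)
        res = measure_jsw(ls2, fw2, p.pixel_spacing)
        assert any("cross" in w for w in res.warnings)
        assert all(c.radius >= 0 for c in res.circles)
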