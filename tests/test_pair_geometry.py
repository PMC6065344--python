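"""Line parameters, parallel/crisscross pair rules, and segment intersection."""

import math

import numpy as np
import pytest
from shapely.geometry import LineString

from conftest import make_mark, segment_mark
from microwear.classification import classify_all
from microwear.image_io import WorkingArea
from microwear.pair_geometry import (
    all_pair_relations,
    line_params,
    pair_relation,
    segment_intersects,
    write_pairs,
)

WA200 = WorkingArea((100.0, 100.0), 200.0)


class TestLineParams:
    @pytest.mark.parametrize(
        "p1,p2,slope,intercept,vertical",
        [((0, 0), (10, 0), 0.0, 0.0, False),
         ((0, 0), (0, 10), None, 0.0, True),
         ((0, 1), (2, 5), 2.0, 1.0, False)],
    )
    def test_known_lines(self, p1, p2, slope, intercept, vertical):
        m = segment_mark("a", p1, p2)
        lp = line_params(m)
        assert (lp.slope, lp.vertical) == (slope, vertical)
        assert lp.intercept == pytest.approx(intercept)
        assert lp.from_mark == "a"

    def test_line_passes_through_endpoints(self, rng):
        for i in range(50):
            a, b = rng.uniform(0, 200, 2), rng.uniform(0, 200, 2)
            if np.allclose(a, b):
                continue
            lp = line_params(segment_mark(f"m{i}", a, b))
            for p in (a, b):
                if lp.vertical:
                    assert abs(p[0] - lp.intercept) < 1e-9
                else:
                    assert abs(p[1] - (lp.slope * p[0] + lp.intercept)) < 1e-7


class TestPairRelation:
    def test_exactly_parallel_lines(self):
        a = segment_mark("a", (0, 0), (20, 0))
        b = segment_mark("b", (0, 10), (20, 10))
        r = pair_relation(a, b, WA200)
        assert r.relation == "parallel"
        assert r.intersection is None and r.angle_deg is None

    def test_perpendicular_cross_at_origin(self):
        a = segment_mark("a", (-10, 0), (10, 0))
        b = segment_mark("b", (0, -10), (0, 10))
        r = pair_relation(a, b, WA200)
        assert r.relation == "crisscross"
        assert r.intersection == pytest.approx((0.0, 0.0))
        assert r.angle_deg == pytest.approx(90.0)

    def test_far_intersection_counts_as_parallel(self):
        # lines y=0 and y=0.01x+10 meet at (-1000, 0): ~1000 um from both
        # segments, beyond T = 2 x 200 = 400 um
        a = segment_mark("a", (0, 0), (20, 0))
        b = segment_mark("b", (0, 10), (20, 10.2))
        assert pair_relation(a, b, WA200).relation == "parallel"
        # a large enough multiplier flips it to crisscross
        assert pair_relation(a, b, WA200, multiplier=6.0).relation == "crisscross"

    def test_symmetric_under_swap(self, rng):
        for i in range(100):
            a = segment_mark("a", rng.uniform(0, 200, 2), rng.uniform(0, 200, 2))
            b = segment_mark("b", rng.uniform(0, 200, 2), rng.uniform(0, 200, 2))
            assert pair_relation(a, b, WA200) == pair_relation(b, a, WA200)

    def test_angle_range_and_rotation_invariance(self, rng):
        for i in range(50):
            pts = rng.uniform(20, 180, size=(4, 2))
            a, b = segment_mark("a", pts[0], pts[1]), segment_mark("b", pts[2], pts[3])
            r = pair_relation(a, b, WA200)
            phi = rng.uniform(0, 2 * math.pi)
            R = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
            c = np.array([100.0, 100.0])
            rot = lambda p: tuple(R @ (np.asarray(p) - c) + c)
            ar = segment_mark("a", rot(pts[0]), rot(pts[1]))
            br = segment_mark("b", rot(pts[2]), rot(pts[3]))
            rr = pair_relation(ar, br, WA200)
            assert rr.relation == r.relation
            if r.relation == "crisscross":
                assert 0.0 < r.angle_deg <= 90.0
                assert rr.angle_deg == pytest.approx(r.angle_deg, abs=1e-6)

    def test_intersecting_segments_always_crisscross(self, rng):
        wa_tiny = WorkingArea((100, 100), 1e-6)  # T barely above zero
        found = 0
        for i in range(200):
            a = segment_mark("a", rng.uniform(0, 200, 2), rng.uniform(0, 200, 2))
            b = segment_mark("b", rng.uniform(0, 200, 2), rng.uniform(0, 200, 2))
            if segment_intersects(a, b):
                found += 1
                assert pair_relation(a, b, WA200).relation == "crisscross"
                assert pair_relation(a, b, wa_tiny).relation == "crisscross"
        assert found > 10

    def test_multiplier_monotone(self, rng):
        for i in range(100):
            a = segment_mark("a", rng.uniform(0, 200, 2), rng.uniform(0, 200, 2))
            b = segment_mark("b", rng.uniform(0, 400, 2), rng.uniform(0, 400, 2))
            prev = None
            for mult in (0.1, 0.5, 1.0, 2.0, 10.0, 1000.0):
                rel = pair_relation(a, b, WA200, multiplier=mult).relation
                if prev == "crisscross":
                    assert rel == "crisscross"
                prev = rel


class TestSegmentIntersects:
    def test_perpendicular_cross(self):
        assert segment_intersects(
            segment_mark("a", (-10, 0), (10, 0)), segment_mark("b", (0, -10), (0, 10))
        )

    def test_parallel_offset_segments(self):
        assert not segment_intersects(
            segment_mark("a", (0, 0), (20, 0)), segment_mark("b", (0, 10), (20, 10))
        )

    def test_collinear_overlap_and_touching_endpoints(self):
        assert segment_intersects(
            segment_mark("a", (0, 0), (10, 0)), segment_mark("b", (5, 0), (20, 0))
        )
        assert segment_intersects(
            segment_mark("a", (0, 0), (10, 0)), segment_mark("b", (10, 0), (10, 10))
        )
        assert not segment_intersects(
            segment_mark("a", (0, 0), (10, 0)), segment_mark("b", (11, 0), (20, 0))
        )

    def test_agrees_with_independent_geometry_library(self, rng):
        for i in range(1000):
            p = rng.integers(0, 21, size=(4, 2)).astype(float)
            if np.array_equal(p[0], p[1]) or np.array_equal(p[2], p[3]):
                continue
            a, b = segment_mark("a", p[0], p[1]), segment_mark("b", p[2], p[3])
            expected = LineString([p[0], p[1]]).intersects(LineString([p[2], p[3]]))
            assert segment_intersects(a, b) == expected, p


def brute_force_rasterized_overlap(a, b, n=4001, tol=8e-3):
    """Oracle: densely sample one segment, measure exact distance to the other."""
    pa = np.linspace(a.p1, a.p2, n)
    q1, q2 = np.asarray(b.p1), np.asarray(b.p2)
    v = q2 - q1
    t = np.clip(((pa - q1) @ v) / (v @ v), 0.0, 1.0)
    d = np.linalg.norm(pa - (q1 + t[:, None] * v), axis=1)
    return bool(d.min() < tol)


class TestRasterizedOracle:
    def test_1000_random_pairs_agree(self, rng):
        checked = 0
        while checked < 1000:
            p = rng.integers(0, 21, size=(4, 2)).astype(float)
            if np.array_equal(p[0], p[1]) or np.array_equal(p[2], p[3]):
                continue
            a, b = segment_mark("a", p[0], p[1]), segment_mark("b", p[2], p[3])
            assert segment_intersects(a, b) == brute_force_rasterized_overlap(a, b), p
            checked += 1


class TestAllPairRelations:
    def _scratches(self, n, rng, jitter=30.0):
        marks = [
            make_mark(f"s{i:02d}", rng.uniform(30, 80), rng.uniform(0.5, 2.5),
                      angle_deg=rng.uniform(0, 180) if jitter > 90 else rng.normal(30, jitter),
                      center=rng.uniform(50, 150, 2))
            for i in range(n)
        ]
        return marks, classify_all(marks)

    def test_zero_or_one_scratch_gives_empty(self, rng):
        for n in (0, 1):
            marks, cls = self._scratches(n, rng)
            assert all_pair_relations(marks, cls, WA200).results == []

    def test_three_mutually_crossing(self):
        marks = [
            segment_mark("a", (50, 100), (150, 100)),
            segment_mark("b", (100, 50), (100, 150)),
            segment_mark("c", (60, 60), (140, 140)),
        ]
        cls = classify_all(marks)
        res = all_pair_relations(marks, cls, WA200).results
        assert len(res) == 3
        assert all(r.relation == "crisscross" for r in res)

    def test_pits_excluded_and_count_is_binomial(self, rng):
        marks, _ = self._scratches(34, rng)
        marks += [make_mark(f"p{i}", 6, 5, center=(100 + i, 100)) for i in range(5)]
        cls = classify_all(marks)
        res = all_pair_relations(marks, cls, WA200).results
        assert len(res) == 34 * 33 // 2 == 561
        assert all(r.relation in ("parallel", "crisscross") for r in res)
        ids = {r.id_a for r in res} | {r.id_b for r in res}
        assert not any(i.startswith("p") for i in ids)
        # deterministic ordering and brute-force double-loop equivalence
        assert res == sorted(res, key=lambda r: (r.id_a, r.id_b))
        scratches = sorted((m for m in marks if m.mark_id.startswith("s")),
                           key=lambda m: m.mark_id)
        brute = [
            pair_relation(scratches[i], scratches[j], WA200)
            for i in range(len(scratches)) for j in range(i + 1, len(scratches))
        ]
        assert sorted(brute, key=lambda r: (r.id_a, r.id_b)) == res

    def test_pairs_csv_export(self, tmp_path, rng):
        marks, cls = self._scratches(5, rng)
        ps = all_pair_relations(marks, cls, WA200)
        out = tmp_path / "pairs.csv"
        write_pairs(ps, out)
        header = out.read_text().splitlines()[0]
        assert header == "id_a,id_b,relation,ix,iy,angle_deg"
        assert len(out.read_text().splitlines()) == 11
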