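"""Fracture-line extraction, matching and minimal-area stitching."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaparea3d as g3
from gaparea3d import gap_core
from gaparea3d.gap_core import (CurvePair, FractureLine,
                                extract_fracture_lines, match_fracture_lines,
                                total_gap_area, triangulate_gap, zigzag_area)

from conftest import make_flat_spec, marked_patches, random_polyline


def brute_force_min_area(pa, pb):
    """Exhaustive minimum over all monotone stitchings of two polylines.

    A stitching is an interleaving of advances along each polyline; with
    n_a + n_b - 2 total moves this enumerates C(n_a + n_b - 2, n_a - 1)
    triangulations. Deliberately independent of the DP implementation.
    """
    na, nb = len(pa), len(pb)
    moves = na - 1 + nb - 1
    best = np.inf
    for a_positions in itertools.combinations(range(moves), na - 1):
        i = j = 0
        area = 0.0
        a_set = set(a_positions)
        for m in range(moves):
            if m in a_set:
                area += 0.5 * np.linalg.norm(
                    np.cross(pa[i + 1] - pa[i], pb[j] - pa[i]))
                i += 1
            else:
                area += 0.5 * np.linalg.norm(
                    np.cross(pb[j + 1] - pb[j], pa[i] - pb[j]))
                j += 1
        best = min(best, area)
    return best


def _line(points, fragment_id=1, index=0):
    return FractureLine(fragment_id, np.asarray(points, dtype=float), index)


class TestExtraction:
    def test_flat_phantom_one_line_per_fragment(self, flat_patches):
        intra = [p for p in flat_patches if p.is_intra]
        all_lines = []
        for p in intra:
            lines = extract_fracture_lines(p, intra, tol=3.0)
            assert len(lines) == 1
            assert lines[0].length == pytest.approx(20.0, abs=0.5)
            all_lines += lines
        assert {ln.fragment_id for ln in all_lines} == {1, 2}

    def test_intact_plate_has_no_fracture_lines(self):
        spec = g3.PhantomSpec(plate_dims=(20.0, 20.0, 10.0))
        _, mask, _ = g3.make_fracture_phantom(spec)
        patches = marked_patches(mask)
        assert extract_fracture_lines(patches[0], patches, tol=3.0) == []

    def test_cross_phantom_yields_two_lines_per_fragment(self, cross_patches):
        intra = [p for p in cross_patches if p.is_intra]
        counts = {}
        total = 0
        for p in intra:
            lines = extract_fracture_lines(p, intra, tol=5.0)
            counts[p.fragment_id] = len(lines)
            total += len(lines)
        assert all(c == 2 for c in counts.values())
        assert total == 8

    def test_closed_patch_without_boundary_rejected(self, flat_patches):
        import dataclasses
        p = flat_patches[0]
        closed = dataclasses.replace(
            p, faces=np.arange(len(p.mesh.triangles)))
        with pytest.raises(ValueError, match="no boundary"):
            gap_core.patch_boundary_loops(closed)


class TestMatching:
    def test_parallel_lines_pair_with_exact_mean_gap(self):
        a = _line([[0, 0, 0], [10, 0, 0]], fragment_id=1)
        b = _line([[0, 3, 0], [10, 3, 0]], fragment_id=2)
        pairs, unmatched = match_fracture_lines([a, b])
        assert len(pairs) == 1 and not unmatched
        assert pairs[0].mean_gap == pytest.approx(3.0)

    def test_greedy_order_leaves_distant_line_unmatched(self):
        a = _line([[0, 0, 0], [10, 0, 0]], fragment_id=1)
        b = _line([[0, 2, 0], [10, 2, 0]], fragment_id=2)
        c = _line([[0, 9, 0], [10, 9, 0]], fragment_id=3)
        pairs, unmatched = match_fracture_lines([a, b, c])
        assert len(pairs) == 1
        assert {pairs[0].line_a.fragment_id, pairs[0].line_b.fragment_id} == {1, 2}
        assert [ln.fragment_id for ln in unmatched] == [3]

    def test_no_pair_under_match_limit_warns(self):
        a = _line([[0, 0, 0], [10, 0, 0]], fragment_id=1)
        b = _line([[0, 50, 0], [10, 50, 0]], fragment_id=2)
        with pytest.warns(UserWarning, match="match limit"):
            pairs, unmatched = match_fracture_lines([a, b])
        assert pairs == [] and len(unmatched) == 2

    def test_same_fragment_lines_never_pair(self):
        a = _line([[0, 0, 0], [10, 0, 0]], fragment_id=1, index=0)
        b = _line([[0, 1, 0], [10, 1, 0]], fragment_id=1, index=1)
        with pytest.warns(UserWarning):
            pairs, unmatched = match_fracture_lines([a, b])
        assert pairs == []

    def test_cross_phantom_pairs_each_cut(self, cross_patches):
        intra = [p for p in cross_patches if p.is_intra]
        lines = []
        for p in intra:
            lines += extract_fracture_lines(p, intra, tol=5.0)
        pairs, unmatched = match_fracture_lines(lines)
        assert len(pairs) == 4 and not unmatched
        got = {tuple(sorted((pr.line_a.fragment_id, pr.line_b.fragment_id)))
               for pr in pairs}
        assert got == {(1, 2), (3, 4), (1, 3), (2, 4)}


class TestTriangulation:
    def test_parallel_rectangle_area(self):
        a = _line([[0, 0, 0], [10, 0, 0]], 1)
        b = _line([[0, 2, 0], [10, 2, 0]], 2)
        surf = triangulate_gap(CurvePair(a, b, mean_gap=2.0))
        assert surf.area == pytest.approx(20.0, rel=1e-6)

    def test_coincident_lines_have_zero_area(self):
        a = _line([[0, 0, 0], [10, 0, 0]], 1)
        b = _line([[0, 0, 0], [10, 0, 0]], 2)
        surf = triangulate_gap(CurvePair(a, b, mean_gap=0.0))
        assert surf.area == pytest.approx(0.0, abs=1e-9)

    def test_reversed_line_gives_same_area(self):
        rng = np.random.default_rng(11)
        a = _line(random_polyline(rng, 5), 1)
        b = _line(random_polyline(rng, 6), 2)
        b_rev = _line(b.points[::-1].copy(), 2)
        s1 = triangulate_gap(CurvePair(a, b, 0.0))
        s2 = triangulate_gap(CurvePair(a, b_rev, 0.0))
        assert s1.area == pytest.approx(s2.area, rel=1e-9)

    def test_swapping_lines_gives_same_area(self):
        rng = np.random.default_rng(12)
        a = _line(random_polyline(rng, 6), 1)
        b = _line(random_polyline(rng, 5), 2)
        s1 = triangulate_gap(CurvePair(a, b, 0.0))
        s2 = triangulate_gap(CurvePair(b, a, 0.0))
        assert s1.area == pytest.approx(s2.area, rel=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_dp_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        na = int(rng.integers(2, 7))
        nb = int(rng.integers(2, 7))
        pa = random_polyline(rng, na)
        pb = random_polyline(rng, nb)
        # disable resampling/reversal so the lattices coincide
        surf = triangulate_gap(
            CurvePair(_line(pa, 1), _line(pb, 2), 0.0), step=None)
        straight = (np.linalg.norm(pa[0] - pb[0])
                    + np.linalg.norm(pa[-1] - pb[-1]))
        crossed = (np.linalg.norm(pa[0] - pb[-1])
                   + np.linalg.norm(pa[-1] - pb[0]))
        if crossed < straight:
            pb = pb[::-1]
        assert surf.area == pytest.approx(brute_force_min_area(pa, pb),
                                          rel=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_dp_never_beaten_by_zigzag(self, seed):
        rng = np.random.default_rng(100 + seed)
        pair = CurvePair(_line(random_polyline(rng, 8), 1),
                         _line(random_polyline(rng, 7), 2), 0.0)
        assert triangulate_gap(pair).area <= zigzag_area(pair) + 1e-9

    def test_triangle_vertices_come_from_source_lines(self):
        a = _line([[0, 0, 0], [5, 0, 0], [10, 0, 0]], 1)
        b = _line([[0, 2, 0], [10, 2, 0]], 2)
        surf = triangulate_gap(CurvePair(a, b, 2.0), step=None)
        src = np.vstack([a.points, b.points])
        for tri in surf.triangles:
            for v in tri:
                assert min(np.linalg.norm(src - v, axis=1)) < 1e-9


class TestTotals:
    def test_single_pair_total(self):
        a = _line([[0, 0, 0], [20, 0, 0]], 1)
        b = _line([[0, 3, 0], [20, 3, 0]], 2)
        surf = triangulate_gap(CurvePair(a, b, 3.0))
        res = total_gap_area([surf], case_id="t")
        assert res.total_area == pytest.approx(60.0, rel=1e-6)
        assert res.per_pair_areas == [surf.area]

    def test_empty_result_flags_no_displacement(self):
        res = total_gap_area([], case_id="t")
        assert res.total_area == 0.0
        assert res.no_displacement

    def test_cross_phantom_total_near_analytic(self):
        # {40, 40, 0, 0} mm^2 across the two cuts -> 80 mm^2 within 5%
        from conftest import make_cross_spec
        spec = make_cross_spec(spacing=0.25)
        _, mask, truth = g3.make_fracture_phantom(spec)
        patches = marked_patches(mask)
        res = gap_core.compute_gap_area(patches, tol=5.0)
        assert truth.expected_gap_area_total == pytest.approx(80.0)
        assert res.total_area == pytest.approx(80.0, rel=0.05)


class TestInvariances:
    def test_rigid_motion_of_assembly_preserves_total(self, flat_patches):
        intra = [p for p in flat_patches if p.is_intra]
        lines = []
        for p in intra:
            lines += extract_fracture_lines(p, intra, tol=3.0)
        pairs, _ = match_fracture_lines(lines)
        base = sum(triangulate_gap(p).area for p in pairs)

        theta = np.deg2rad(33.0)
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0],
                        [0, 0, 1.0]])
        shift = np.array([7.0, -4.0, 2.5])
        moved = [FractureLine(ln.fragment_id, ln.points @ rot.T + shift,
                              ln.index) for ln in lines]
        pairs2, _ = match_fracture_lines(moved)
        total2 = sum(triangulate_gap(p).area for p in pairs2)
        assert abs(total2 - base) / base < 1e-3

    def test_total_area_strictly_increasing_in_displacement(self):
        totals = []
        for d in (0.5, 1.0, 2.0, 3.5, 5.0):
            spec = make_flat_spec(d=d)
            _, mask, _ = g3.make_fracture_phantom(spec)
            res = gap_core.compute_gap_area(marked_patches(mask),
                                            tol=max(3.0, d + 1.0))
            totals.append(res.total_area)
        assert all(b > a for a, b in zip(totals, totals[1:]))

    def test_area_insensitive_to_resampling_step(self):
        rng = np.random.default_rng(2)
        a = _line(np.cumsum(rng.uniform(0.2, 1.0, size=(12, 3)), axis=0), 1)
        b = _line(a.points + np.array([0.0, 2.5, 0.0]), 2)
        fine = triangulate_gap(CurvePair(a, b, 2.5), step=0.1)
        default = triangulate_gap(CurvePair(a, b, 2.5), step=0.5)
        assert default.area == pytest.approx(fine.area, rel=0.02)


class TestResampling:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50),
                              st.floats(-50, 50)),
                    min_size=2, max_size=12),
           st.floats(0.1, 2.0))
    def test_resample_preserves_endpoints_length_and_step(self, pts, step):
        points = np.asarray(pts, dtype=float)
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        total = float(seg.sum())
        out = gap_core.resample_polyline(points, step)
        assert np.allclose(out[0], points[0])
        assert np.allclose(out[-1], points[-1])
        out_seg = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert out_seg.max() <= step + 1e-9 or total == 0
        # resampling follows the chord, so it can only shorten the curve
        assert out_seg.sum() <= total + 1e-9
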