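import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import radtract as rt
from radtract.core_io import GridReference
from radtract.streamlines import quickbundles, resample_polyline

from oracles import arc_length_point, mdf_bruteforce, rasterize_fine


def line(p0, p1, n=2):
    return rt.Streamline(np.linspace(np.asarray(p0, float), np.asarray(p1, float), n))


def tract(streamlines, shape=(20, 20, 20)):
    return rt.Tractogram(list(streamlines), GridReference(shape, np.eye(4)))


class TestResample:
    def test_straight_segment(self):
        s = rt.resample_streamline(line((0, 0, 0), (0, 0, 10)), 3)
        assert np.allclose(s.points[:, 2], [0, 5, 10])

    def test_n2_returns_endpoints(self):
        s = rt.Streamline(np.array([[0.0, 0, 0], [3, 0, 0], [3, 4, 0], [9, 9, 9]]))
        r = rt.resample_streamline(s, 2)
        assert np.allclose(r.points, [s.points[0], s.points[-1]])

    def test_l_shape_midpoint_at_corner(self):
        s = rt.Streamline(np.array([[0.0, 0, 0], [10, 0, 0], [10, 10, 0]]))
        r = rt.resample_streamline(s, 3)
        assert np.allclose(r.points[1], arc_length_point(s.points, 0.5))
        assert np.allclose(r.points[1], [10, 0, 0])

    def test_rejects_n_below_2(self):
        with pytest.raises(ValueError):
            rt.resample_streamline(line((0, 0, 0), (1, 1, 1)), 1)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(5, 60), st.integers(0, 1000))
    def test_endpoints_and_arclength_preserved(self, n, seed):
        # smooth helical polyline: arc length of a resampling can only
        # shrink by corner cutting, which must stay under 1% for n at or
        # above the original point count
        rng = np.random.default_rng(seed)
        theta = np.linspace(0, np.pi, 16)
        radius = rng.uniform(2, 6)
        pts = np.stack(
            [radius * np.cos(theta), radius * np.sin(theta), np.linspace(0, 10, 16)],
            axis=1,
        )
        s = rt.Streamline(pts)
        r = rt.resample_streamline(s, n)
        assert np.array_equal(r.points[0], pts[0])
        assert np.array_equal(r.points[-1], pts[-1])
        if n >= len(pts):
            orig = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
            new = np.sum(np.linalg.norm(np.diff(r.points, axis=0), axis=1))
            assert abs(new - orig) / orig < 0.01


class TestMDF:
    def test_identical_zero_unflipped(self):
        s = line((0, 0, 0), (0, 0, 10), 5)
        d, flipped = rt.mdf_distance(s, s, n=8)
        assert d == 0 and not flipped

    def test_reversed_copy_detected(self):
        s = rt.Streamline(np.array([[0.0, 0, 0], [1, 0, 0], [5, 3, 0]]))
        d, flipped = rt.mdf_distance(s, s.reversed(), n=8)
        assert d < 1e-9 and flipped

    def test_translation_distance(self):
        a = line((0, 0, 0), (0, 0, 10), 5)
        b = line((3, 0, 0), (3, 0, 10), 5)
        d, flipped = rt.mdf_distance(a, b, n=6)
        exp, exp_f = mdf_bruteforce(
            resample_polyline(a.points, 6), resample_polyline(b.points, 6)
        )
        assert d == pytest.approx(exp) == pytest.approx(3.0)
        assert flipped == exp_f

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 500))
    def test_symmetric_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        a = rt.Streamline(np.cumsum(rng.normal(0.5, 0.3, (6, 3)), axis=0))
        b = rt.Streamline(np.cumsum(rng.normal(0.5, 0.3, (9, 3)), axis=0))
        dab, _ = rt.mdf_distance(a, b)
        dba, _ = rt.mdf_distance(b, a)
        assert dab >= 0
        assert dab == pytest.approx(dba, rel=1e-9)


class TestOrientation:
    def make_mixed_tract(self):
        fwd = [line((x, 0, 0), (x, 0, 10), 5) for x in range(3)]
        rev = [s.reversed() for s in (line((x, 0, 0), (x, 0, 10), 5) for x in (3, 4))]
        return tract(fwd + rev)

    def roi_at_origin(self):
        m = np.zeros((20, 20, 20), dtype=np.uint8)
        m[0:6, 0, 0] = 1
        return rt.BinaryMask(m, np.eye(4))

    def test_start_roi_aligns_and_is_idempotent(self):
        t = self.make_mixed_tract()
        roi = self.roi_at_origin()
        out = rt.orient_by_start_roi(t, roi)
        for s in out.streamlines:
            assert s.points[0, 2] == 0  # all start at z=0 near the ROI
        again = rt.orient_by_start_roi(out, roi)
        for a, b in zip(out.streamlines, again.streamlines):
            assert np.array_equal(a.points, b.points)

    def test_equidistant_keeps_input_order(self):
        m = np.zeros((20, 20, 20), dtype=np.uint8)
        m[10, 10, 5] = 1  # equidistant from both ends of the segment below
        roi = rt.BinaryMask(m, np.eye(4))
        s = line((10, 0, 0), (10, 0, 10), 3)
        out = rt.orient_by_start_roi(tract([s]), roi)
        assert np.array_equal(out.streamlines[0].points, s.points)

    def test_empty_roi_raises(self):
        roi = rt.BinaryMask(np.zeros((5, 5, 5), dtype=np.uint8), np.eye(4))
        with pytest.raises(rt.EmptyInputError):
            rt.orient_by_start_roi(tract([line((0, 0, 0), (0, 0, 4))]), roi)

    def test_centerline_orientation_fixes_flipped_half(self):
        t = self.make_mixed_tract()
        c = rt.Centerline(np.linspace([2, 0, 0], [2, 0, 10], 5))
        out = rt.orient_by_centerline(t, c)
        for s in out.streamlines:
            assert s.points[0, 2] < s.points[-1, 2]
        twice = rt.orient_by_centerline(out, c)
        for a, b in zip(out.streamlines, twice.streamlines):
            assert np.array_equal(a.points, b.points)


class TestCenterline:
    def test_identical_streamlines(self):
        s = line((0, 0, 0), (0, 0, 10), 7)
        c = rt.compute_centerline(tract([s, s, s]), 7)
        assert np.allclose(c.points, s.points)

    def test_offset_pair_averages_to_axis(self):
        a = line((1, 0, 0), (1, 0, 10), 5)
        b = line((-1, 0, 0), (-1, 0, 10), 5)
        c = rt.compute_centerline(tract([a, b]), 5)
        assert np.allclose(c.points[:, 0], 0)
        assert np.allclose(c.points[:, 2], [0, 2.5, 5, 7.5, 10])

    def test_single_streamline_is_itself(self):
        s = rt.Streamline(np.array([[0.0, 0, 0], [5, 0, 0], [5, 5, 0]]))
        c = rt.compute_centerline(tract([s]), 9)
        assert np.allclose(c.points, resample_polyline(s.points, 9))

    def test_empty_raises(self):
        with pytest.raises(rt.EmptyInputError):
            rt.compute_centerline(tract([]), 5)


class TestReduce:
    def test_below_target_passthrough(self):
        sls = [line((x, 0, 0), (x, 0, 10), 4) for x in range(40)]
        t = tract(sls, shape=(50, 20, 20))
        out = rt.reduce_streamlines(t, target=50)
        assert len(out) == 40
        for a, b in zip(sls, out.streamlines):
            assert np.array_equal(a.points, b.points)

    def test_well_separated_groups_recovered(self):
        rng = np.random.default_rng(5)
        groups = []
        offsets = [(0, 0), (100, 0), (0, 100), (100, 100), (200, 0)]
        for ox, oy in offsets:
            for _ in range(200):
                jitter = rng.normal(0, 0.2, size=(6, 3))
                base = np.linspace([ox, oy, 0], [ox, oy, 30], 6)
                groups.append(rt.Streamline(base + jitter))
        t = tract(groups, shape=(250, 150, 40))
        out = rt.reduce_streamlines(t, target=5, band=0.1)
        assert len(out) == 5
        # each representative sits near exactly one group center
        reps = np.stack([s.points.mean(axis=0)[:2] for s in out.streamlines])
        centers = np.asarray(offsets, float)
        d = np.linalg.norm(reps[:, None] - centers[None], axis=2)
        assert np.array_equal(np.sort(d.argmin(axis=1)), np.arange(5))
        assert d.min(axis=1).max() < 5

    def test_identical_streamlines_collapse(self):
        pts = np.linspace([0, 0, 0], [0, 0, 10], 6)
        t = tract([rt.Streamline(pts.copy()) for _ in range(10)])
        out = rt.reduce_streamlines(t, target=1)
        assert len(out) == 1
        assert np.allclose(
            resample_polyline(out.streamlines[0].points, 6), pts, atol=1e-9
        )

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        sls = [
            rt.Streamline(np.linspace([x, 0, 0], [x + rng.normal(), 0, 10], 5))
            for x in rng.uniform(0, 30, 80)
        ]
        t = tract(sls, shape=(40, 20, 20))
        a = rt.reduce_streamlines(t, target=20, seed=3)
        b = rt.reduce_streamlines(t, target=20, seed=3)
        assert len(a) == len(b)
        for sa, sb in zip(a.streamlines, b.streamlines):
            assert np.array_equal(sa.points, sb.points)
        assert 1 <= len(a) <= max(22, len(t))

    def test_rejects_bad_target(self):
        t = tract([line((0, 0, 0), (0, 0, 5))])
        with pytest.raises(ValueError):
            rt.reduce_streamlines(t, target=0)


class TestTraversal:
    def grid(self, shape=(10, 10, 10)):
        return rt.ScalarImage(np.zeros(shape), np.eye(4))

    def test_axial_through_centers(self):
        s = line((5, 5, 0), (5, 5, 9), 5)
        assert rt.count_traversed_voxels(s, self.grid()) == 10

    def test_contained_in_one_voxel(self):
        s = line((2.1, 2.1, 2.1), (2.3, 2.2, 2.2))
        assert rt.count_traversed_voxels(s, self.grid()) == 1

    def test_diagonal_matches_fine_oracle(self):
        s = line((0, 0, 0), (2.99, 2.99, 2.99), 4)
        grid = self.grid((3, 3, 3))
        expected = rasterize_fine(s.points, (3, 3, 3), np.eye(4), step=0.05)
        assert rt.count_traversed_voxels(s, grid) == len(expected)

    def test_reversal_invariance(self, rng):
        pts = np.cumsum(rng.normal(0.8, 0.3, (10, 3)), axis=0) + 2
        s = rt.Streamline(pts)
        grid = self.grid((30, 30, 30))
        assert rt.count_traversed_voxels(s, grid) == rt.count_traversed_voxels(
            s.reversed(), grid
        )

    def test_outside_grid_returns_zero(self):
        s = line((50, 50, 50), (60, 60, 60))
        assert rt.count_traversed_voxels(s, self.grid()) == 0
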