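"""Cleaning, junction, edge removal, interpolation, rediscretization, angles."""

import math

import numpy as np
import pytest

from mesotrack.trajectories import (
    Segment,
    UnresolvedConflictError,
    auto_clean,
    compute_distances,
    compute_speeds,
    compute_turning_angles,
    detect_conflicts,
    interpolate,
    join_trajectories,
    pixel_to_cm,
    rediscretize,
    remove_edge_points,
)

from conftest import make_traj


class TestConflicts:
    def test_disjoint_supports_no_conflict(self):
        a = make_traj(range(0, 10), tid="a")
        b = make_traj(range(20, 30), tid="b")
        assert detect_conflicts([a, b]) == []

    def test_overlap_length_and_separation(self):
        a = make_traj(range(0, 20), xs=np.zeros(20), ys=np.zeros(20), tid="a")
        b = make_traj(range(10, 30), xs=np.full(20, 100.0), ys=np.zeros(20), tid="b")
        (c,) = detect_conflicts([a, b])
        assert c.overlap_s == 10
        assert c.min_separation_px == pytest.approx(100.0)

    def test_three_mutual_overlaps_give_three_pairs(self):
        trajs = [make_traj(range(0, 10), xs=np.full(10, 100.0 * k), tid=f"t{k}") for k in range(3)]
        assert len(detect_conflicts(trajs)) == 3


class TestAutoClean:
    def test_small_noise_overlap_removed_from_shorter(self):
        long = make_traj(range(500), xs=np.zeros(500), ys=np.zeros(500), tid="long")
        noise = make_traj([100, 101, 102], xs=np.full(3, 400.0), ys=np.zeros(3), tid="noise")
        cleaned = auto_clean([long, noise], max_auto_points=10)
        by_id = {t.trajectory_id: t for t in cleaned}
        assert len(by_id["long"]) == 500
        assert "noise" not in by_id  # all 3 points were conflicting

    def test_large_overlap_halts_with_review(self, tmp_path):
        a = make_traj(range(100), xs=np.zeros(100), tid="a")
        b = make_traj(range(50, 150), xs=np.full(100, 400.0), tid="b")
        review = tmp_path / "review.csv"
        with pytest.raises(UnresolvedConflictError) as exc:
            auto_clean([a, b], max_auto_points=10, review_path=review)
        assert review.exists()
        assert str(review) in str(exc.value)

    def test_exclusion_list_resolves_large_overlap(self):
        a = make_traj(range(100), xs=np.zeros(100), tid="a")
        b = make_traj(range(50, 150), xs=np.full(100, 400.0), tid="b")
        cleaned = auto_clean([a, b], max_auto_points=10, exclusion_list=["b"])
        assert [t.trajectory_id for t in cleaned] == ["a"]

    def test_close_simultaneous_tracks_both_deleted(self):
        # 20 px < 5 cm * 6.82 px/cm = 34.1 px: ambiguous identity
        a = make_traj(range(100), xs=np.zeros(100), ys=np.zeros(100), tid="a")
        b = make_traj(range(80, 180), xs=np.zeros(100), ys=np.full(100, 20.0), tid="b")
        cleaned = auto_clean([a, b], max_auto_points=1000)
        by_id = {t.trajectory_id: t for t in cleaned}
        assert len(by_id["a"]) == 80 and by_id["a"].t_s.max() == 79
        assert len(by_id["b"]) == 80 and by_id["b"].t_s.min() == 100

    def test_just_beyond_5cm_not_mutually_deleted(self):
        a = make_traj(range(5), xs=np.zeros(5), ys=np.zeros(5), tid="a")
        b = make_traj(range(5), xs=np.zeros(5), ys=np.full(5, 35.0), tid="b")  # > 34.1 px
        cleaned = auto_clean([a, b], max_auto_points=10)
        # the small-overlap rule applies instead; on equal lengths the first
        # id is treated as the noise track and loses its conflicting points
        assert {t.trajectory_id for t in cleaned} == {"b"}
        (surv,) = cleaned
        assert len(surv) == 5


class TestJunction:
    @pytest.mark.parametrize(
        "gap_t,gap_d,t_g,d_g,merged",
        [
            (5, 20.0, 10, 50.0, True),
            (11, 20.0, 10, 50.0, False),
            (5, 60.0, 10, 50.0, False),
            (10, 50.0, 10, 50.0, True),  # boundary: <= is inclusive
        ],
    )
    def test_junction_criteria(self, gap_t, gap_d, t_g, d_g, merged):
        a = make_traj([0, 1, 2], xs=[0.0, 1.0, 2.0], ys=[0.0, 0.0, 0.0], tid="a")
        b = make_traj(
            [2 + gap_t, 3 + gap_t],
            xs=[2.0 + gap_d, 3.0 + gap_d],
            ys=[0.0, 0.0],
            tid="b",
        )
        out = join_trajectories([a, b], t_g_s=t_g, d_g_px=d_g)
        assert len(out) == (1 if merged else 2)
        if merged:
            assert out[0].trajectory_id == "a"
            assert len(out[0]) == 5

    def test_nearest_candidate_preferred(self):
        a = make_traj([0, 1], xs=[0.0, 1.0], tid="a")
        near = make_traj([4], xs=[3.0], tid="near")
        far = make_traj([8], xs=[4.0], tid="far")
        out = join_trajectories([a, near, far], t_g_s=10, d_g_px=50.0)
        # a joins near (smaller time gap), then the merged end joins far
        assert len(out) == 1 and out[0].trajectory_id == "a"


class TestEdgeRemoval:
    def test_center_trajectory_unchanged(self, small_arena):
        t = make_traj(range(5), xs=np.full(5, 100.0), ys=np.full(5, 100.0))
        (out,) = remove_edge_points([t], small_arena)
        assert len(out) == 5

    def test_near_edge_point_removed(self, small_arena):
        t = make_traj([0, 1, 2], xs=[100.0, 30.0, 100.0], ys=[100.0, 100.0, 100.0])
        out = remove_edge_points([t], small_arena)
        assert sum(len(o) for o in out) == 2

    def test_center_edge_center_splits(self, small_arena):
        xs = [100.0] * 5 + [10.0] * 3 + [100.0] * 5
        t = make_traj(range(13), xs=xs, ys=np.full(13, 100.0), tid="t")
        out = remove_edge_points([t], small_arena)
        assert len(out) == 2
        assert [len(o) for o in out] == [5, 5]
        assert {o.trajectory_id for o in out} == {"t#0", "t#1"}

    def test_buffer_boundary_is_half_open(self, small_arena):
        # x = 35 survives, x = 34 does not; x = width-35 does not survive
        t = make_traj([0, 1, 2], xs=[35.0, 34.0, 165.0], ys=np.full(3, 100.0))
        out = remove_edge_points([t], small_arena)
        assert sum(len(o) for o in out) == 1


class TestInterpolate:
    def test_linear_midpoint(self):
        t = make_traj([0, 2], xs=[0.0, 2.0], ys=[0.0, 4.0])
        out = interpolate(t)
        assert list(out.t_s) == [0, 1, 2]
        assert out.x_px[1] == pytest.approx(1.0)
        assert out.y_px[1] == pytest.approx(2.0)
        assert list(out.interpolated) == [False, True, False]

    def test_gap_free_unchanged(self):
        t = make_traj(range(5))
        out = interpolate(t)
        assert np.array_equal(out.t_s, t.t_s)
        assert not out.interpolated.any()

    def test_uniform_speed_over_long_gap(self):
        t = make_traj([0, 10], xs=[0.0, 10.0], ys=[0.0, 0.0])
        out = interpolate(t)
        assert len(out) == 11
        assert np.allclose(np.diff(out.x_px), 1.0)
        assert out.interpolated[1:-1].all()


def anchor_walk_oracle(times, tau):
    """Naive re-anchoring walk over a sorted list of observed times."""
    times = sorted(times)
    segments = []
    k = 0
    while k < len(times) and times[k] + tau <= times[-1]:
        target = times[k] + tau
        if target in times:
            segments.append((times[k], target))
            k = times.index(target)
        else:
            k += 1
    return segments


class TestRediscretize:
    TIMES = [0, 1, 2, 3, 4, 6, 7, 10, 20, 21]

    def _traj(self, times=None):
        times = self.TIMES if times is None else times
        return make_traj(times, xs=np.asarray(times, float), ys=np.zeros(len(times)))

    def test_anchor_walk_example(self):
        segs = rediscretize(self._traj(), redisc_s=5, interpolate_flag=False)
        assert [(s.t_start, s.t_end) for s in segs] == [(1, 6)]

    def test_with_interpolation_example(self):
        segs = rediscretize(self._traj(), redisc_s=5, interpolate_flag=True)
        assert [(s.t_start, s.t_end) for s in segs] == [(0, 5), (5, 10), (10, 15), (15, 20)]
        # the points at t=5 and t=15 were missing: segments crossing them are flagged
        assert all(s.contains_interpolated for s in segs)
        # endpoint positions come from the interpolated trajectory
        assert segs[0].x_end == pytest.approx(5.0)

    def test_gap_free_61_points_tau_60(self):
        segs = rediscretize(self._traj(list(range(61))), redisc_s=60)
        assert len(segs) == 1

    def test_too_short_returns_empty(self):
        assert rediscretize(self._traj([0, 1, 2]), redisc_s=5) == []

    def test_fixed_grid_variant(self):
        segs = rediscretize(self._traj(), redisc_s=5, grid_mode="fixed")
        # absolute grid 0,5,10,15,20: only (15,20) has both endpoints... neither 5 nor 15 observed
        assert [(s.t_start, s.t_end) for s in segs] == []
        segs2 = rediscretize(self._traj([0, 2, 5, 10, 12, 15]), redisc_s=5, grid_mode="fixed")
        assert [(s.t_start, s.t_end) for s in segs2] == [(0, 5), (5, 10), (10, 15)]

    def test_anchor_walk_matches_oracle_on_random_time_sets(self, rng):
        for _ in range(300):
            n = rng.integers(2, 40)
            times = np.sort(rng.choice(200, size=n, replace=False))
            tau = int(rng.integers(1, 15))
            traj = self._traj(list(times))
            got = [(s.t_start, s.t_end) for s in rediscretize(traj, redisc_s=tau)]
            assert got == anchor_walk_oracle(list(map(int, times)), tau)

    def test_segments_have_exact_duration(self, rng):
        times = np.sort(rng.choice(100, size=30, replace=False))
        for tau in (1, 5, 10):
            for interp in (False, True):
                segs = rediscretize(self._traj(list(times)), tau, interpolate_flag=interp)
                assert all(s.duration_s == tau for s in segs)

    def test_without_interpolation_endpoints_are_observed(self, rng):
        times = np.sort(rng.choice(100, size=30, replace=False))
        segs = rediscretize(self._traj(list(times)), 5)
        tset = set(map(int, times))
        for s in segs:
            assert s.t_start in tset and s.t_end in tset
            assert not s.contains_interpolated


class TestDistancesSpeedsAngles:
    def seg(self, p0, p1, t0=0, tau=1):
        return Segment(t0, t0 + tau, p0[0], p0[1], p1[0], p1[1])

    def test_pythagoras_and_calibration(self):
        s = self.seg((0.0, 0.0), (3.0, 4.0))
        assert compute_distances([s])[0] == pytest.approx(5.0)
        assert compute_speeds([s], 1)[0] == pytest.approx(5.0 / 6.82)

    def test_zero_displacement_zero_speed(self):
        s = self.seg((1.0, 1.0), (1.0, 1.0))
        assert compute_speeds([s], 1)[0] == 0.0

    def test_calibration_identity(self):
        s = self.seg((0.0, 0.0), (6.82, 0.0))
        assert compute_speeds([s], 1)[0] == pytest.approx(1.0)

    def test_left_turn_positive(self):
        # east then "north" = decreasing image y; y-up convention -> +pi/2
        s1 = self.seg((0.0, 0.0), (1.0, 0.0), t0=0)
        s2 = self.seg((1.0, 0.0), (1.0, -1.0), t0=1)
        (a,) = compute_turning_angles([s1, s2])
        assert a.value_rad == pytest.approx(math.pi / 2)
        assert a.t_vertex == 1

    def test_collinear_zero(self):
        s1 = self.seg((0.0, 0.0), (1.0, 1.0), t0=0)
        s2 = self.seg((1.0, 1.0), (2.0, 2.0), t0=1)
        (a,) = compute_turning_angles([s1, s2])
        assert a.value_rad == pytest.approx(0.0)

    def test_exact_reversal_is_plus_pi(self):
        s1 = self.seg((0.0, 0.0), (1.0, 0.0), t0=0)
        s2 = self.seg((1.0, 0.0), (0.0, 0.0), t0=1)
        (a,) = compute_turning_angles([s1, s2])
        assert a.value_rad == pytest.approx(math.pi)
        assert a.value_rad > 0

    def test_non_adjacent_segments_produce_no_angle(self):
        s1 = self.seg((0.0, 0.0), (1.0, 0.0), t0=0)
        s2 = self.seg((5.0, 0.0), (6.0, 1.0), t0=3)  # starts at t=3, s1 ends at t=1
        assert compute_turning_angles([s1, s2]) == []

    def test_zero_length_segment_skipped_with_counter(self):
        s1 = self.seg((0.0, 0.0), (0.0, 0.0), t0=0)
        s2 = self.seg((0.0, 0.0), (1.0, 0.0), t0=1)
        angles, skipped = compute_turning_angles([s1, s2], return_skipped=True)
        assert angles == [] and skipped == 1

    def test_pixel_to_cm_calibration_values(self):
        assert round(pixel_to_cm(50.0), 1) == 7.3
        assert round(pixel_to_cm(35.0), 1) == 5.1
        assert pixel_to_cm(0.0) == 0.0
        with pytest.raises(ValueError):
            pixel_to_cm(10.0, px_per_cm=0.0)


class TestPipelineOrderProperties:
    def test_junction_and_edge_removal_do_not_commute(self, small_arena):
        # fragment A ends near the edge, fragment B starts near the edge:
        # junction first bridges them; edge removal first leaves two pieces
        a = make_traj([0, 1], xs=[100.0, 20.0], ys=[100.0, 100.0], tid="a")
        b = make_traj([3, 4], xs=[22.0, 100.0], ys=[100.0, 100.0], tid="b")
        join_then_edge = remove_edge_points(join_trajectories([a, b], 10, 50.0), small_arena)
        edge_then_join = join_trajectories(remove_edge_points([a, b], small_arena), 10, 50.0)
        n_join_first = len(join_then_edge)
        n_edge_first = len(edge_then_join)
        assert n_join_first != n_edge_first

    @pytest.mark.parametrize("tau", [1, 5, 10])
    @pytest.mark.parametrize("interp", [False, True])
    def test_straight_line_speed_invariant_to_procedure(self, tau, interp):
        v = 2.5  # px/s
        t = make_traj(range(61), xs=v * np.arange(61.0), ys=np.zeros(61))
        segs = rediscretize(t, tau, interpolate_flag=interp)
        speeds = compute_speeds(segs, tau)
        assert np.allclose(speeds, v / 6.82)
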