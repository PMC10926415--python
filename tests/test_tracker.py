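"""Tracking: maximum images, assignment, linking, trajectory filters."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from streaktrack.geometry import Annotation, Circle, PointMark, Polyline
from streaktrack.synthetic import SceneConfig, render_sequence, score_tracking
from streaktrack.tracker import (
    Detection,
    TrackingConfig,
    Trajectory,
    build_trajectories,
    filter_trajectories,
    link_detections,
    pairwise_maximum,
    roi_filter,
    solve_assignment,
    track_batch,
    trajectories_to_dataframe,
    trajectories_to_via,
    trajectory_direction,
)
from tests.conftest import make_linear_track


def pl(*xy):
    return Polyline(np.array(xy, dtype=float))


def det(shape, pair_index, score=0.9):
    return Detection(Annotation(shape, score), score, pair_index)


class TestPairwiseMaximum:
    def test_idempotent_on_identical_frames(self):
        a = np.random.default_rng(0).uniform(0, 255, (16, 16))
        (out,) = pairwise_maximum([a, a])
        assert np.array_equal(out, a)

    def test_elementwise_max(self):
        a = np.array([[0, 50], [100, 10]], dtype=float)
        b = np.array([[30, 40], [90, 200]], dtype=float)
        a = np.pad(a, ((0, 14), (0, 14)))
        b = np.pad(b, ((0, 14), (0, 14)))
        (out,) = pairwise_maximum([a, b])
        assert out[0, 0] == 30 and out[0, 1] == 50 and out[1, 0] == 100 and out[1, 1] == 200

    def test_five_frames_give_four_images_each_bounding_inputs(self):
        rng = np.random.default_rng(1)
        frames = [rng.uniform(0, 255, (16, 16)) for _ in range(5)]
        out = pairwise_maximum(frames)
        assert len(out) == 4
        for i, img in enumerate(out):
            assert (img >= frames[i]).all() and (img >= frames[i + 1]).all()

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            pairwise_maximum([np.zeros((16, 16))])
        with pytest.raises(ValueError, match="mismatched"):
            pairwise_maximum([np.zeros((16, 16)), np.zeros((16, 17))])


class TestAssignment:
    def test_prefers_anti_diagonal(self):
        pairs = solve_assignment(np.array([[1.0, 2.0], [2.0, 4.0]]))
        assert pairs == {(0, 1), (1, 0)}  # total 4 beats diagonal's 5

    def test_diagonal_zeroes(self):
        assert solve_assignment(np.array([[0.0, 9.0], [9.0, 0.0]])) == {(0, 0), (1, 1)}

    def test_threshold_pruning_after_optimum(self):
        cost = np.array([[1.0, 50.0], [50.0, 1.0]])
        assert solve_assignment(cost, threshold=10.0) == {(0, 0), (1, 1)}
        assert solve_assignment(cost, threshold=0.5) == set()

    def test_empty(self):
        assert solve_assignment(np.empty((0, 3))) == set()

    def test_rectangular_rows_can_go_unmatched(self):
        # second row's only affordable column is taken; padding at the
        # threshold lets it stay unmatched instead of forcing a bad link
        cost = np.array([[1.0, 100.0], [2.0, 100.0]])
        pairs = solve_assignment(cost, threshold=10.0)
        assert pairs == {(0, 0)}

    def test_optimal_against_brute_force(self):
        rng = np.random.default_rng(99)
        for _ in range(500):
            n = int(rng.integers(1, 8))
            cost = rng.uniform(0, 100, (n, n))
            pairs = solve_assignment(cost)
            total = sum(cost[r, c] for r, c in pairs)
            best = min(
                sum(cost[i, p[i]] for i in range(n))
                for p in itertools.permutations(range(n))
            )
            assert total == pytest.approx(best, abs=1e-9)


class TestLinking:
    def test_abutting_blurs_link_far_one_does_not(self):
        a = det(pl((0, 0), (40, 0)), 0)
        far = det(pl((300, 300), (340, 300)), 0)
        b = det(pl((40, 0), (80, 0)), 1)
        assert link_detections([a, far], [b]) == {(0, 0)}

    def test_threshold_is_inclusive(self):
        # crossing at right angles at midpoints, 5 px half-lengths: d_M exactly 5
        a = det(pl((0, 0), (10, 0)), 0)
        b = det(pl((5, -5), (5, 5)), 1)
        assert link_detections([a], [b], TrackingConfig(dm_threshold=5.0)) == {(0, 0)}
        assert link_detections([a], [b], TrackingConfig(dm_threshold=4.99)) == set()

    def test_non_polylines_never_link(self):
        c = Detection(Annotation(Circle(5, 5, 3), 0.9), 0.9, 0)
        p = Detection(Annotation(PointMark(5, 5), 0.9), 0.9, 1)
        b = det(pl((0, 0), (10, 0)), 1)
        assert link_detections([c], [b, p]) == set()

    def test_empty_side(self):
        assert link_detections([det(pl((0, 0), (10, 0)), 0)], []) == set()


class TestBuildTrajectories:
    def test_single_insect_chain(self):
        # one insect: overlapping collinear detections across 4 pair images
        per_pair = [[det(pl((40 * t, 0), (40 * t + 80, 0)), t)] for t in range(4)]
        trajs = build_trajectories(per_pair)
        assert len(trajs) == 1 and trajs[0].n_detections == 4

    def test_two_separated_insects_no_swap(self):
        per_pair = [
            [
                det(pl((40 * t, 0), (40 * t + 80, 0)), t),
                det(pl((40 * t, 500), (40 * t + 80, 500)), t),
            ]
            for t in range(3)
        ]
        trajs = build_trajectories(per_pair)
        assert sorted(t.n_detections for t in trajs) == [3, 3]
        for traj in trajs:
            ys = {d.polyline.ys[0] for d in traj.detections}
            assert len(ys) == 1  # never mixes rows

    def test_partition_conservation(self):
        rng = np.random.default_rng(4)
        per_pair = [
            [det(pl(tuple(rng.uniform(0, 500, 2)), tuple(rng.uniform(0, 500, 2))), t) for _ in range(3)]
            for t in range(5)
        ]
        trajs = build_trajectories(per_pair)
        assert sum(t.n_detections for t in trajs) == 15
        ids = [id(d) for t in trajs for d in t.detections]
        assert len(ids) == len(set(ids))

    def test_singleton(self):
        trajs = build_trajectories([[det(pl((0, 0), (10, 0)), 0)], []])
        assert len(trajs) == 1 and trajs[0].n_detections == 1

    def test_trajectory_invariants(self):
        with pytest.raises(ValueError, match="increase by exactly 1"):
            Trajectory([det(pl((0, 0), (1, 0)), 0), det(pl((0, 0), (1, 0)), 2)])


class TestFilters:
    def mk(self, scores, start=0):
        return Trajectory([det(pl((10 * i, 0), (10 * i + 20, 0)), start + i, s) for i, s in enumerate(scores)])

    def test_short_trajectory_removed_despite_high_score(self):
        assert filter_trajectories([self.mk([0.99, 0.99])]) == []

    def test_mean_score_boundary(self):
        keep = self.mk([0.9, 0.7, 0.9])       # mean 0.8333
        drop = self.mk([0.9, 0.6, 0.8])       # mean 0.7667
        out = filter_trajectories([keep, drop], TrackingConfig(min_mean_score=0.8))
        assert out == [keep]

    def test_filters_only_remove_and_survivors_satisfy_predicates(self):
        rng = np.random.default_rng(8)
        trajs = [self.mk(list(rng.uniform(0.5, 1.0, rng.integers(1, 6)))) for _ in range(30)]
        cfg = TrackingConfig()
        out = filter_trajectories(trajs, cfg)
        assert len(out) <= len(trajs)
        for t in out:
            assert t.n_detections >= cfg.min_detections
            assert t.mean_score >= cfg.min_mean_score

    def test_roi_vertex_rule(self):
        roi = Circle(0, 0, 100)
        inside = self.mk([0.9] * 3)  # x up to 40, well inside
        boundary = Trajectory([det(pl((0, 0), (100, 0)), 0)])        # vertex at exactly r
        outside = Trajectory([det(pl((0, 0), (101, 0)), 0)])         # vertex at r+1
        out = roi_filter([inside, boundary, outside], roi)
        assert out == [inside, boundary]


class TestDirection:
    def test_axis_aligned(self):
        right = Trajectory([det(pl((0, 0), (10, 0)), 0), det(pl((10, 0), (20, 0)), 1)])
        assert trajectory_direction(right) == pytest.approx(0.0, abs=1e-9)
        down = Trajectory([det(pl((0, 0), (0, 10)), 0), det(pl((0, 10), (0, 20)), 1)])
        assert trajectory_direction(down) == pytest.approx(90.0, abs=1e-9)

    def test_reversed_vertex_order_still_consistent(self):
        # second detection stored end-to-start; orientation chaining fixes it
        traj = Trajectory([det(pl((0, 0), (10, 0)), 0), det(pl((20, 0), (10, 0)), 1)])
        assert trajectory_direction(traj) == pytest.approx(0.0, abs=1e-9)

    def test_undefined_for_single_detection(self):
        with pytest.raises(ValueError, match="undefined"):
            trajectory_direction(Trajectory([det(pl((0, 0), (10, 0)), 0)]))

    def test_synthetic_track_at_30_degrees(self):
        cfg = SceneConfig(width=480, height=360, fps=30.0, exposure=1 / 30.0, n_frames=30, seed=21)
        v = 400.0
        track = make_linear_track(
            0,
            start=(60.0, 60.0),
            velocity=(v * math.cos(math.radians(30)), v * math.sin(math.radians(30))),
            frames_visible=(0, 29),
        )
        frames, _ = render_sequence([track], cfg)
        result = track_batch(frames)
        assert len(result.trajectories) == 1
        assert trajectory_direction(result.trajectories[0]) == pytest.approx(30.0, abs=3.0)


class TestTrackBatch:
    def test_two_insect_clip_recovered(self, mini_clip):
        frames, truths, tracks, cfg = mini_clip
        result = track_batch(frames)
        score = score_tracking(result.trajectories, tracks, cfg)
        assert len(result.trajectories) == 2
        assert score.n_recovered == 2 and score.n_identity_swaps == 0

    def test_insect_seen_too_briefly_is_filtered(self):
        # one visible frame -> two half-blur detections, below min_detections
        cfg = SceneConfig(width=480, height=320, fps=30.0, exposure=1 / 30.0, n_frames=10, seed=13)
        track = make_linear_track(0, start=(200.0, 150.0), velocity=(400.0, 0.0), frames_visible=(4, 4))
        frames, _ = render_sequence([track], cfg)
        result = track_batch(frames)
        assert result.trajectories == []
        assert result.n_detections >= 1  # it was detected, then filtered

    def test_roi_drops_peripheral_track(self, mini_clip):
        frames, truths, tracks, cfg = mini_clip
        roi = Circle(240, 80, 250)  # encloses the y=80 lane, clips the y=240 one
        result = track_batch(frames, TrackingConfig(roi=roi))
        assert len(result.trajectories) == 1
        assert result.n_after_score_filter == 2  # ROI did the final cut

    def test_outputs_round_trip(self, mini_clip):
        frames, *_ = mini_clip
        result = track_batch(frames)
        df = trajectories_to_dataframe(result.trajectories)
        assert set(df.columns) == {"trajectory_id", "pair_index", "score", "direction_deg", "n_detections"}
        assert len(df) == sum(t.n_detections for t in result.trajectories)
        project = trajectories_to_via(result.trajectories, [f"max_{t}.png" for t in range(len(frames) - 1)])
        n_regions = sum(len(r.regions) for r in project.records)
        assert n_regions == len(df)
        tids = {e["trajectory_id"] for r in project.records for e in r.region_extra}
        assert tids == {"0", "1"}
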