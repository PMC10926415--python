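"""Classical streak detector: segmentation, polyline fitting, classification."""

from __future__ import annotations

import numpy as np
import pytest

from streaktrack.detector import (
    DegenerateMaskError,
    DetectorParams,
    Frame,
    StreakMask,
    annotate_image,
    classify_and_annotate,
    detection_score,
    mask_to_polyline,
    segment_streaks,
    to_grayscale,
)
from streaktrack.geometry import bbox_of, polyline_length
from streaktrack.synthetic import SceneConfig, render_still
from tests.conftest import make_linear_track


def noise_frame(rng, h=240, w=320, level=10.0, sigma=2.0):
    return np.clip(rng.normal(level, sigma, (h, w)), 0, 255)


class TestSegmentation:
    def test_dark_noise_frame_yields_nothing(self):
        frame = noise_frame(np.random.default_rng(0))
        assert segment_streaks(frame) == []

    def test_uniform_frame_yields_nothing(self):
        assert segment_streaks(np.full((64, 64), 37.0)) == []

    def test_single_interior_streak(self, still_scene):
        frame, truth, track, cfg = still_scene
        masks = segment_streaks(frame)
        assert len(masks) == 1
        assert not masks[0].touches_border
        assert masks[0].area >= 200

    def test_streak_exiting_edge_touches_border(self):
        cfg = SceneConfig(width=320, height=240, fps=5.0, exposure=0.2, seed=3)
        track = make_linear_track(start=(250.0, 120.0), velocity=(600.0, 0.0))
        frame, truth = render_still([track], cfg)
        masks = segment_streaks(frame)
        assert len(masks) == 1
        assert masks[0].touches_border
        assert truth[0].annotation.kind == "circle"

    def test_frame_validation(self):
        with pytest.raises(ValueError):
            Frame(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            Frame(np.full((16, 16), 300.0))


class TestScore:
    def test_arithmetic(self):
        mask = StreakMask(np.array([[5, 5]]), mean_intensity=130.0, touches_border=False)
        frame = np.full((64, 64), 10.0)
        assert detection_score(mask, frame) == pytest.approx(120 / 245, abs=1e-6)

    def test_extremes(self):
        frame0 = np.zeros((64, 64))
        top = StreakMask(np.array([[1, 1]]), 255.0, False)
        assert detection_score(top, frame0) == 1.0
        flat = StreakMask(np.array([[1, 1]]), 0.0, False)
        assert detection_score(flat, frame0) == 0.0
        saturated = np.full((64, 64), 255.0)
        assert detection_score(top, saturated) == 0.0

    def test_monotone_in_contrast(self):
        frame = np.full((64, 64), 10.0)
        scores = [
            detection_score(StreakMask(np.array([[1, 1]]), m, False), frame)
            for m in (50.0, 120.0, 200.0)
        ]
        assert scores == sorted(scores)


class TestMaskToPolyline:
    def test_recovers_diagonal_line(self):
        coords = np.array([(y, x) for x in range(21) for y in [x]])  # y = x
        mask = StreakMask(coords, 200.0, False)
        poly = mask_to_polyline(mask, order=1, n_vertices=5)
        assert np.allclose(poly.xs, poly.ys, atol=0.5)
        ends = {tuple(np.round(poly.vertices[0])), tuple(np.round(poly.vertices[-1]))}
        assert ends == {(0.0, 0.0), (20.0, 20.0)}

    def test_recovers_parabola(self):
        xs = np.arange(0, 41)
        rows, cols = [], []
        for x in xs:
            y = 0.05 * (x - 20.0) ** 2
            for dy in (-1, 0, 1):  # 3 px thick band
                rows.append(y + dy)
                cols.append(x)
        mask = StreakMask(np.column_stack([rows, cols]), 200.0, False)
        poly = mask_to_polyline(mask, order=2, n_vertices=20)
        # compare fitted curve against the generating parabola
        expected = 0.05 * (poly.xs - 20.0) ** 2
        assert np.allclose(poly.ys, expected, atol=0.75)

    def test_polyline_stays_near_mask_bbox(self, still_scene):
        frame, truth, track, cfg = still_scene
        (mask,) = segment_streaks(frame)
        poly = mask_to_polyline(mask)
        box = bbox_of(poly)
        assert box.x_min >= mask.pixels[:, 1].min() - 2
        assert box.x_max <= mask.pixels[:, 1].max() + 2
        assert box.y_min >= mask.pixels[:, 0].min() - 2
        assert box.y_max <= mask.pixels[:, 0].max() + 2

    def test_degenerate_mask_raises(self):
        mask = StreakMask(np.array([[5, 5], [5, 5], [5, 5]]), 200.0, False)
        with pytest.raises(DegenerateMaskError):
            mask_to_polyline(mask)

    def test_too_few_abscissae_falls_back_to_line(self):
        # two distinct principal-axis positions cannot support order 2
        coords = np.array([[0, 0], [0, 3], [1, 0], [1, 3]])
        mask = StreakMask(coords, 200.0, False)
        poly = mask_to_polyline(mask, order=2, n_vertices=4)
        assert poly.n_vertices == 4  # straight-line fallback still yields a chain


class TestClassification:
    def test_interior_streak_is_polyline(self, still_scene):
        frame, truth, track, cfg = still_scene
        (mask,) = segment_streaks(frame)
        ann = classify_and_annotate(mask, frame)
        assert ann.kind == "polyline"
        assert 0.0 <= ann.score <= 1.0

    def test_border_streak_is_circle_enclosing_mask(self):
        cfg = SceneConfig(width=320, height=240, fps=5.0, exposure=0.2, seed=3)
        track = make_linear_track(start=(250.0, 120.0), velocity=(600.0, 0.0))
        frame, _ = render_still([track], cfg)
        (mask,) = segment_streaks(frame)
        ann = classify_and_annotate(mask, frame)
        assert ann.kind == "circle"
        d = np.hypot(mask.pixels[:, 1] - ann.shape.cx, mask.pixels[:, 0] - ann.shape.cy)
        assert d.max() <= ann.shape.r + 1e-6

    def test_tiny_interior_blob_is_point(self):
        rng = np.random.default_rng(1)
        frame = noise_frame(rng)
        frame[100:104, 100:106] = 220.0  # 4x6 blob, extent below min_polyline_length
        (mask,) = segment_streaks(frame)
        ann = classify_and_annotate(mask, frame)
        assert ann.kind == "point"
        assert ann.shape.cx == pytest.approx(102.5, abs=1.0)
        assert ann.shape.cy == pytest.approx(101.5, abs=1.0)


class TestAnnotateImage:
    def test_three_streaks_all_polylines(self):
        cfg = SceneConfig(width=480, height=360, fps=5.0, exposure=0.2, seed=9)
        tracks = [
            make_linear_track(0, start=(40.0, 60.0), velocity=(700.0, 0.0)),
            make_linear_track(1, start=(40.0, 180.0), velocity=(800.0, 50.0)),
            make_linear_track(2, start=(40.0, 300.0), velocity=(600.0, -40.0)),
        ]
        frame, truth = render_still(tracks, cfg)
        anns = annotate_image(frame)
        assert [a.kind for a in anns] == ["polyline"] * 3

    def test_empty_frame(self):
        assert annotate_image(noise_frame(np.random.default_rng(2))) == []

    def test_interior_plus_clipped(self):
        cfg = SceneConfig(width=480, height=360, fps=5.0, exposure=0.2, seed=10)
        tracks = [
            make_linear_track(0, start=(100.0, 100.0), velocity=(700.0, 0.0)),
            make_linear_track(1, start=(400.0, 280.0), velocity=(700.0, 0.0)),  # exits right
        ]
        frame, _ = render_still(tracks, cfg)
        kinds = sorted(a.kind for a in annotate_image(frame))
        assert kinds == ["circle", "polyline"]

    def test_deterministic_and_sorted(self, still_scene):
        frame, *_ = still_scene
        first = annotate_image(frame)
        second = annotate_image(frame)
        assert first == second
        xs = [bbox_of(a).x_min for a in first]
        assert xs == sorted(xs)

    def test_fitted_length_close_to_truth(self, still_scene):
        frame, truth, track, cfg = still_scene
        (ann,) = annotate_image(frame)
        ratio = polyline_length(ann.shape) / truth[0].arc_length
        assert 0.8 <= ratio <= 1.25


class TestGrayscale:
    def test_channel_max_default(self):
        rgb = np.zeros((8, 8, 3))
        rgb[..., 2] = 200.0
        assert to_grayscale(rgb).max() == 200.0

    def test_luminance_option(self):
        rgb = np.zeros((8, 8, 3))
        rgb[..., 2] = 200.0
        assert to_grayscale(rgb, "luminance").max() == pytest.approx(0.114 * 200)


class TestParams:
    def test_vertices_must_cover_order(self):
        with pytest.raises(ValueError):
            DetectorParams(polyline_order=3, vertices_per_polyline=3)

    def test_defaults_match_documented_values(self):
        p = DetectorParams()
        assert p.polyline_order == 2  # low-order curves suffice for flight blurs
        assert p.vertices_per_polyline >= p.polyline_order + 1
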