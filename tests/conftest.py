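"""Shared fixtures: small ground-truthed scenes built at test time."""

from __future__ import annotations

import math

import numpy as np
import pytest

from streaktrack.synthetic import GroundTruthTrack, SceneConfig, render_sequence, render_still


def make_linear_track(
    identity: int = 0,
    start=(60.0, 120.0),
    velocity=(600.0, 0.0),
    wingbeat_hz: float = 54.0,
    baseline: float = 200.0,
    amplitude: float = 55.0,
    frames_visible=(0, 0),
) -> GroundTruthTrack:
    """A straight constant-speed track with explicit kinematics."""
    coeffs = np.array(
        [[start[0], velocity[0], 0.0], [start[1], velocity[1], 0.0]], dtype=float
    )
    speed = math.hypot(*velocity)
    return GroundTruthTrack(
        identity, coeffs, speed, wingbeat_hz, amplitude, baseline, frames_visible
    )


@pytest.fixture
def still_scene():
    """One bright linear streak in a small frame, with its truth."""
    cfg = SceneConfig(width=320, height=240, fps=5.0, exposure=0.2, seed=7)
    track = make_linear_track(start=(40.0, 120.0), velocity=(800.0, 100.0))
    frame, truth = render_still([track], cfg)
    return frame, truth, track, cfg


@pytest.fixture
def mini_clip():
    """A 40-frame clip of two well-separated insects, with truth."""
    cfg = SceneConfig(width=480, height=320, fps=30.0, exposure=1.0 / 30.0, n_frames=40, seed=11)
    tracks = [
        make_linear_track(0, start=(30.0, 80.0), velocity=(330.0, 0.0), frames_visible=(0, 39)),
        make_linear_track(1, start=(30.0, 240.0), velocity=(310.0, 10.0), frames_visible=(0, 39)),
    ]
    frames, truths = render_sequence(tracks, cfg)
    return frames, truths, tracks, cfg
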