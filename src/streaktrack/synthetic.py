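"""Seeded generator of ground-truthed night-capture fixtures.

Emulates the statistical structure of long-exposure night imagery of
flying insects: a dark, Gaussian-noisy sky background crossed by bright
streaks whose paths are low-order polynomials in time and whose
intensity is modulated by a raised sinusoid at the insect's wingbeat
frequency.  Multi-frame sequences render each frame's exposure window
back-to-back, so with ``exposure == 1/fps`` an individual's blurs in
consecutive frames abut end-to-end — precisely the property the tracker
exploits via pairwise maximum images.

Every render is deterministic given the tracks, the scene configuration
and its seed, and returns exact ground truth (per-track polylines, or an
enclosing circle when a blur is clipped by the frame edge) so detector,
tracker and wingbeat estimates can be scored against known answers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, Field
from scipy.spatial.distance import cdist

from .geometry import Annotation, Circle, Polyline, min_enclosing_circle

__all__ = [
    "GroundTruthTrack",
    "SceneConfig",
    "TruthAnnotation",
    "render_still",
    "render_sequence",
    "pair_truth",
    "random_scene",
    "TrackingScore",
    "score_tracking",
]


class SceneConfig(BaseModel):
    """Capture settings of a simulated night scene.

    Defaults mirror a wildlife camera filming the night sky: 1080p,
    30 frames per second, and a long 1/9 s still exposure.  For video
    rendering the exposure must not exceed the frame interval; stills
    ignore ``fps``.
    """

    width: int = Field(1920, ge=64)
    height: int = Field(1080, ge=64)
    fps: float = Field(30.0, gt=0)
    exposure: float = Field(1.0 / 9.0, gt=0)
    n_frames: int = Field(1, ge=1)
    background_level: float = Field(10.0, ge=0, le=255)
    noise_sigma: float = Field(2.0, ge=0)
    streak_width: float = Field(3.0, gt=0)
    seed: int = 0


@dataclass
class GroundTruthTrack:
    """One simulated insect.

    ``coeffs`` is a (2, 3) array: position(t) = c0 + c1*t + c2*t**2 per
    axis (x then y), t in seconds from the start of the clip.  Intensity
    along the blur is ``baseline + amplitude * (0.5 + 0.5 * sin(2*pi*
    wingbeat_hz * t))`` — a raised sinusoid, so the blur never goes fully
    dark between wingbeats.  ``frames_visible`` is the inclusive frame
    range in which the insect is rendered.
    """

    identity: int
    coeffs: np.ndarray
    speed: float
    wingbeat_hz: float
    amplitude: float
    baseline: float
    frames_visible: Tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (2, 3):
            raise ValueError(f"coeffs must be (2, 3), got {self.coeffs.shape}")
        if self.speed <= 0:
            raise ValueError("speed must be > 0")
        if self.wingbeat_hz < 0:
            raise ValueError("wingbeat_hz must be >= 0")
        if self.baseline + self.amplitude > 255 + 1e-9:
            raise ValueError("baseline + amplitude must be <= 255")
        if self.frames_visible[1] < self.frames_visible[0]:
            raise ValueError("frames_visible must be an inclusive (first, last) range")

    def position(self, t: np.ndarray) -> np.ndarray:
        """Positions (n, 2) at times t (seconds)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        powers = np.stack([np.ones_like(t), t, t * t])  # (3, n)
        return (self.coeffs @ powers).T

    def intensity(self, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return self.baseline + self.amplitude * (
            0.5 + 0.5 * np.sin(2.0 * math.pi * self.wingbeat_hz * t)
        )


@dataclass(frozen=True)
class TruthAnnotation:
    """Ground truth for one track in one rendered exposure."""

    identity: int
    frame: int
    annotation: Annotation
    wingbeat_hz: float
    arc_length: float
    n_cycles: float


def _track_truth(
    track: GroundTruthTrack, t0: float, t1: float, cfg: SceneConfig, frame: int
) -> Optional[TruthAnnotation]:
    """Exact truth annotation for the blur over [t0, t1], or None if off-frame."""
    times = np.linspace(t0, t1, 64)
    pts = track.position(times)
    arc = float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))
    inside = (
        (pts[:, 0] >= 0)
        & (pts[:, 0] <= cfg.width - 1)
        & (pts[:, 1] >= 0)
        & (pts[:, 1] <= cfg.height - 1)
    )
    n_cycles = track.wingbeat_hz * (t1 - t0)
    if not inside.any():
        return None
    if inside.all():
        n_vert = int(np.clip(math.ceil(arc / 5.0) + 1, 2, 64))
        v_times = np.linspace(t0, t1, n_vert)
        verts = track.position(v_times)
        keep = np.ones(len(verts), dtype=bool)
        keep[1:] = np.any(np.diff(verts, axis=0) != 0, axis=1)
        verts = verts[keep]
        if verts.shape[0] < 2:
            return None
        shape: Annotation = Annotation(Polyline(verts))
    else:
        circ = min_enclosing_circle(pts[inside])
        shape = Annotation(Circle(circ.cx, circ.cy, circ.r + cfg.streak_width / 2.0))
    return TruthAnnotation(track.identity, frame, shape, track.wingbeat_hz, arc, n_cycles)


def _stamp_track(canvas: np.ndarray, track: GroundTruthTrack, t0: float, t1: float, cfg: SceneConfig) -> None:
    """Max-composite the blur of one track over [t0, t1] onto the canvas.

    The path is sampled at <= 0.25 px arc steps; each sample stamps a
    soft-edged disc of diameter ``streak_width`` at the instantaneous
    intensity, composited by maximum (a bright moving body occludes the
    sky behind it).
    """
    probe = track.position(np.linspace(t0, t1, 64))
    arc = float(np.sum(np.hypot(*np.diff(probe, axis=0).T)))
    n = max(2, int(math.ceil(arc / 0.25)) + 1)
    times = np.linspace(t0, t1, n)
    pts = track.position(times)
    vals = track.intensity(times)

    h, w = canvas.shape
    r = cfg.streak_width / 2.0
    half = int(math.ceil(r + 0.5))
    offs = np.arange(-half, half + 1)
    ox, oy = np.meshgrid(offs, offs)  # (k, k)

    base = np.floor(pts)  # (n, 2) x, y
    px = base[:, 0][:, None, None] + ox[None]  # (n, k, k) pixel x
    py = base[:, 1][:, None, None] + oy[None]
    dist = np.hypot(px - pts[:, 0][:, None, None], py - pts[:, 1][:, None, None])
    # pixel-coverage approximation of a hard-edged disc: full inside r,
    # linear falloff across the boundary half-pixel
    cover = np.clip((r + 0.5 - dist) / 0.5, 0.0, 1.0)
    stamp = cover * vals[:, None, None]

    valid = (px >= 0) & (px < w) & (py >= 0) & (py < h) & (stamp > 0)
    if not valid.any():
        return
    np.maximum.at(
        canvas,
        (py[valid].astype(int), px[valid].astype(int)),
        stamp[valid],
    )


def _render_frame(
    tracks: Sequence[GroundTruthTrack],
    cfg: SceneConfig,
    frame: int,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, List[TruthAnnotation]]:
    t0 = frame / cfg.fps
    t1 = t0 + cfg.exposure
    background = rng.normal(cfg.background_level, cfg.noise_sigma, (cfg.height, cfg.width))
    canvas = np.zeros_like(background)
    truths: List[TruthAnnotation] = []
    for track in tracks:
        if not (track.frames_visible[0] <= frame <= track.frames_visible[1]):
            continue
        truth = _track_truth(track, t0, t1, cfg, frame)
        if truth is None:
            warnings.warn(
                f"track {track.identity} entirely outside frame {frame}; excluded from truth",
                stacklevel=3,
            )
            continue
        _stamp_track(canvas, track, t0, t1, cfg)
        truths.append(truth)
    out = np.clip(np.maximum(background, canvas), 0.0, 255.0)
    return np.rint(out).astype(np.uint8), truths


def render_still(
    tracks: Sequence[GroundTruthTrack],
    cfg: SceneConfig,
    frame: int = 0,
) -> Tuple[np.ndarray, List[TruthAnnotation]]:
    """Render one exposure starting at ``frame / fps``.

    Returns the uint8 frame and exact truth annotations: a polyline per
    fully-visible blur, an enclosing circle per clipped blur.
    """
    rng = np.random.default_rng(cfg.seed)
    return _render_frame(tracks, cfg, frame, rng)


def render_sequence(
    tracks: Sequence[GroundTruthTrack],
    cfg: SceneConfig,
) -> Tuple[List[np.ndarray], List[List[TruthAnnotation]]]:
    """Render ``n_frames`` consecutive exposures.

    Frame i covers [i/fps, i/fps + exposure]; with ``exposure == 1/fps``
    the blurs of one insect abut end-to-end across frames.
    """
    if cfg.n_frames < 2:
        raise ValueError("render_sequence needs n_frames >= 2")
    if cfg.exposure > 1.0 / cfg.fps + 1e-12:
        raise ValueError("sequence exposure must not exceed the frame interval 1/fps")
    rng = np.random.default_rng(cfg.seed)
    frames: List[np.ndarray] = []
    truths: List[List[TruthAnnotation]] = []
    for i in range(cfg.n_frames):
        frame, truth = _render_frame(tracks, cfg, i, rng)
        frames.append(frame)
        truths.append(truth)
    return frames, truths


def pair_truth(
    tracks: Sequence[GroundTruthTrack],
    cfg: SceneConfig,
    pair_index: int,
) -> List[TruthAnnotation]:
    """Truth for the maximum image of frames ``pair_index`` and +1.

    The combined blur spans both exposures, clipped to the frames in
    which the track is actually rendered.
    """
    out: List[TruthAnnotation] = []
    for track in tracks:
        first, last = track.frames_visible
        lo = max(pair_index, first)
        hi = min(pair_index + 1, last)
        if lo > hi:
            continue
        t0 = lo / cfg.fps
        t1 = hi / cfg.fps + cfg.exposure
        truth = _track_truth(track, t0, t1, cfg, pair_index)
        if truth is not None:
            out.append(truth)
    return out


def _truth_points(track: GroundTruthTrack, cfg: SceneConfig, duration: float) -> np.ndarray:
    """Dense path samples over the track's visible window (for overlap checks)."""
    first, last = track.frames_visible
    t0 = first / cfg.fps
    t1 = min(last / cfg.fps + cfg.exposure, duration)
    return track.position(np.linspace(t0, max(t1, t0 + cfg.exposure), 96))


def _interior_runs(inside_by_frame: np.ndarray) -> Tuple[int, int]:
    """Longest run of consecutive True values; (-1, -2) if none."""
    best = (-1, -2)
    start = None
    for i, ok in enumerate(list(inside_by_frame) + [False]):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            if (i - 1) - start > best[1] - best[0]:
                best = (start, i - 1)
            start = None
    return best


def random_scene(
    n_insects: int,
    preset: str = "clean",
    seed: int = 0,
    cfg: Optional[SceneConfig] = None,
    speed_range: Tuple[float, float] = (100.0, 1500.0),
    min_visible_frames: int = 6,
    separation_px: float = 80.0,
    interior_margin: float = 12.0,
) -> Tuple[List[GroundTruthTrack], SceneConfig]:
    """Draw a reproducible scene of ``n_insects`` tracks.

    ``preset="clean"`` gives bright, well-separated, non-crossing tracks
    (pairwise path separation at least ``separation_px``, enforced by
    rejection sampling) whose blurs stay in the frame interior while
    visible; ``preset="hard"`` allows dim tracks and crossings.  Speeds
    are drawn uniformly from ``speed_range`` (px/s), wingbeat frequencies
    from 20-80 Hz, and curvature is a gentle quadratic term.
    """
    if n_insects < 0:
        raise ValueError("n_insects must be >= 0")
    if preset not in ("clean", "hard"):
        raise ValueError(f"unknown preset {preset!r}")
    cfg = cfg if cfg is not None else SceneConfig(seed=seed)
    rng = np.random.default_rng(seed)
    sequence = cfg.n_frames > 1
    duration = cfg.n_frames / cfg.fps if sequence else cfg.exposure

    # Clean scenes model a loosely common flight direction (as in a
    # migration event): near-parallel paths, placed in evenly spaced
    # lanes across the heading normal, can actually satisfy the pairwise
    # separation requirement, whereas independent headings almost always
    # cross somewhere inside the frame.
    scene_heading = rng.uniform(0.0, 2.0 * math.pi)
    scene_normal = np.array([-math.sin(scene_heading), math.cos(scene_heading)])
    centre = np.array([(cfg.width - 1) / 2.0, (cfg.height - 1) / 2.0])
    # width of the frame's projection onto the lane normal
    lane_extent = (
        cfg.width * abs(scene_normal[0])
        + cfg.height * abs(scene_normal[1])
        - 2.0 * interior_margin
    )
    lane_spacing = lane_extent / max(n_insects, 1)
    diag = math.hypot(cfg.width, cfg.height)

    tracks: List[GroundTruthTrack] = []
    accepted_pts: List[np.ndarray] = []
    for identity in range(n_insects):
        for attempt in range(5000):
            speed = rng.uniform(*speed_range)
            if preset == "clean":
                heading = scene_heading + rng.normal(0.0, math.radians(3.0))
            else:
                heading = rng.uniform(0.0, 2.0 * math.pi)
            vel = speed * np.array([math.cos(heading), math.sin(heading)])
            # gentle curvature: lateral deviation up to ~15% of the visible
            # path (capped at 30 px, and in clean scenes at a fraction of
            # the lane spacing so bowed paths cannot close the gap)
            path_est = min(speed * duration, diag)
            cap = min(0.15 * path_est, 30.0)
            if preset == "clean":
                cap = min(cap, max(2.0, 0.15 * lane_spacing))
            deviation = rng.uniform(0.0, cap) * rng.choice([-1.0, 1.0])
            normal = np.array([-vel[1], vel[0]]) / speed
            c2 = deviation / max(path_est / speed, 1e-6) ** 2 * normal
            t_mid = rng.uniform(0.2, 0.8) * duration
            if preset == "clean":
                offset = (identity - (n_insects - 1) / 2.0) * lane_spacing
                offset += rng.uniform(-0.1, 0.1) * lane_spacing
                # slide the anchor along the heading so it stays inside the
                # frame interior without collapsing outer lanes inward
                direction = vel / speed
                base = centre + offset * scene_normal
                lo, hi = -math.inf, math.inf
                for axis, limit in ((0, cfg.width), (1, cfg.height)):
                    lo_a = interior_margin - base[axis]
                    hi_a = (limit - 1 - interior_margin) - base[axis]
                    if abs(direction[axis]) > 1e-9:
                        a, b = lo_a / direction[axis], hi_a / direction[axis]
                        lo, hi = max(lo, min(a, b)), min(hi, max(a, b))
                    elif not (lo_a <= 0.0 <= hi_a):
                        lo, hi = 1.0, 0.0  # lane misses the frame
                if lo > hi:
                    continue
                anchor = base + rng.uniform(0.75 * lo + 0.25 * hi, 0.25 * lo + 0.75 * hi) * direction
            else:
                anchor = np.array(
                    [
                        rng.uniform(0.2 * cfg.width, 0.8 * cfg.width),
                        rng.uniform(0.2 * cfg.height, 0.8 * cfg.height),
                    ]
                )
            c0 = anchor - vel * t_mid - c2 * t_mid * t_mid
            coeffs = np.stack([[c0[0], vel[0], c2[0]], [c0[1], vel[1], c2[1]]])

            wingbeat = rng.uniform(20.0, 80.0)
            if preset == "clean":
                # well-exposed IR-flash blur: near-saturated, modulation rides on top
                baseline = rng.uniform(210.0, 235.0)
                amplitude = 255.0 - baseline
            else:
                baseline = rng.uniform(40.0, 120.0)
                amplitude = rng.uniform(20.0, min(100.0, 255.0 - baseline))

            track = GroundTruthTrack(identity, coeffs, speed, wingbeat, amplitude, baseline)

            # visibility: frames whose whole exposure stays inside the interior box
            m = interior_margin
            n_frames = cfg.n_frames if sequence else 1
            inside = np.zeros(n_frames, dtype=bool)
            for i in range(n_frames):
                ts = np.linspace(i / cfg.fps, i / cfg.fps + cfg.exposure, 32)
                p = track.position(ts)
                inside[i] = bool(
                    (p[:, 0] >= m).all()
                    and (p[:, 0] <= cfg.width - 1 - m).all()
                    and (p[:, 1] >= m).all()
                    and (p[:, 1] <= cfg.height - 1 - m).all()
                )
            first, last = _interior_runs(inside)
            needed = min_visible_frames if sequence else 1
            if last - first + 1 < needed:
                continue
            track.frames_visible = (first, last)

            if preset == "clean" and accepted_pts:
                pts = _truth_points(track, cfg, duration)
                if min(cdist(pts, q).min() for q in accepted_pts) < separation_px:
                    continue
            tracks.append(track)
            accepted_pts.append(_truth_points(track, cfg, duration))
            break
        else:
            raise RuntimeError(
                f"could not place track {identity} after 5000 attempts; "
                "scene too crowded for the requested separation"
            )
    return tracks, cfg


@dataclass
class TrackingScore:
    """How well recovered trajectories match the generator's truth."""

    n_true: int                 # tracks visible long enough to be trackable
    n_trajectories: int
    n_recovered: int            # identities recovered as exactly one pure trajectory
    n_identity_swaps: int       # trajectories mixing two identities
    n_unassigned: int           # detections matching no truth blur

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered / self.n_true if self.n_true else 1.0


def score_tracking(
    trajectories: Sequence,
    tracks: Sequence[GroundTruthTrack],
    cfg: SceneConfig,
    min_detections: int = 3,
    assign_tolerance_px: float = 30.0,
) -> TrackingScore:
    """Assign each trajectory detection to its nearest truth blur and tally.

    A detection is assigned to the truth identity whose combined
    pair-image blur lies nearest (mean point-to-polyline distance below
    ``assign_tolerance_px``).  A trajectory is *pure* if all its
    detections map to one identity; an identity is *recovered* if exactly
    one pure trajectory maps to it.
    """
    from .geometry import points_to_polyline_distance, resample_polyline

    truth_cache = {}

    def truths_at(t: int):
        if t not in truth_cache:
            truth_cache[t] = [
                tr for tr in pair_truth(tracks, cfg, t) if isinstance(tr.annotation.shape, Polyline)
            ]
        return truth_cache[t]

    eligible = {
        tr.identity
        for tr in tracks
        if tr.frames_visible[1] - tr.frames_visible[0] + 1 >= min_detections + 1
    }
    traj_identities: List[set] = []
    n_unassigned = 0
    by_identity: dict = {}
    for traj in trajectories:
        idents = set()
        for det in traj.detections:
            poly = det.polyline
            if poly is None:
                continue
            samples = resample_polyline(poly, 2.0)
            best, best_d = None, math.inf
            for tr in truths_at(det.pair_index):
                d = float(points_to_polyline_distance(samples, tr.annotation.shape).mean())
                if d < best_d:
                    best, best_d = tr.identity, d
            if best is not None and best_d <= assign_tolerance_px:
                idents.add(best)
            else:
                n_unassigned += 1
        traj_identities.append(idents)
        if len(idents) == 1:
            by_identity.setdefault(next(iter(idents)), []).append(traj)
    n_swaps = sum(1 for s in traj_identities if len(s) > 1)
    n_recovered = sum(
        1 for ident in eligible if len(by_identity.get(ident, [])) == 1
    )
    return TrackingScore(
        n_true=len(eligible),
        n_trajectories=len(list(trajectories)),
        n_recovered=n_recovered,
        n_identity_swaps=n_swaps,
        n_unassigned=n_unassigned,
    )
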