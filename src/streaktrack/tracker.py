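"""Detection-based multi-insect tracking over video frames.

A batch of frames is reduced to pairwise maximum images (pixelwise max of
consecutive frames).  Because a flying insect's motion blurs in
consecutive frames abut, its blurs *overlap* in consecutive maximum
images, so detections can be chained without any explicit motion model:
detections in successive maximum images are linked by solving the linear
sum assignment problem with the matching distance d_M as cost, links with
d_M above a threshold are dropped, and the resulting chains are filtered
by length and mean detection score, then optionally constrained to a
circular region of interest (removing the directional bias a rectangular
frame would otherwise impose on displacement statistics).

Only polyline detections carry the path information d_M needs, so circle
and point detections form singleton trajectories that the minimum-length
filter later removes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy.optimize import linear_sum_assignment

from .annotation_io import ImageRecord, ViaProject
from .detector import DetectorParams, Frame, annotate_image, _as_pixels
from .geometry import Annotation, Circle, Polyline, matching_distance, point_to_polyline_distance

__all__ = [
    "Detection",
    "Trajectory",
    "TrackingConfig",
    "TrackingResult",
    "pairwise_maximum",
    "solve_assignment",
    "link_detections",
    "build_trajectories",
    "filter_trajectories",
    "roi_filter",
    "trajectory_direction",
    "track_batch",
    "trajectories_to_dataframe",
    "trajectories_to_via",
]


@dataclass(frozen=True)
class Detection:
    """A scored annotation bound to the maximum image it was found in.

    ``pair_index`` t refers to the maximum of frames t and t+1.
    """

    annotation: Annotation
    score: float
    pair_index: int

    def __post_init__(self) -> None:
        if self.pair_index < 0:
            raise ValueError("pair_index must be >= 0")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")

    @property
    def polyline(self) -> Optional[Polyline]:
        shape = self.annotation.shape
        return shape if isinstance(shape, Polyline) else None


@dataclass
class Trajectory:
    """An ordered chain of detections with consecutive pair indices."""

    detections: List[Detection]

    def __post_init__(self) -> None:
        if not self.detections:
            raise ValueError("Trajectory must contain at least one detection")
        idx = [d.pair_index for d in self.detections]
        if any(b - a != 1 for a, b in zip(idx, idx[1:])):
            raise ValueError(f"pair indices must increase by exactly 1, got {idx}")

    @property
    def n_detections(self) -> int:
        return len(self.detections)

    @property
    def mean_score(self) -> float:
        return float(np.mean([d.score for d in self.detections]))


class TrackingConfig(BaseModel, arbitrary_types_allowed=True):
    dm_threshold: float = Field(40.0, gt=0, description="max d_M (px) for a link")
    min_detections: int = Field(3, gt=0)
    min_mean_score: float = Field(0.8, ge=0, le=1)
    roi: Optional[Circle] = None
    detector: DetectorParams = Field(default_factory=DetectorParams)


def pairwise_maximum(frames: Sequence[Union[Frame, np.ndarray]]) -> List[np.ndarray]:
    """Pixelwise maximum of each consecutive frame pair.

    N frames give N-1 maximum images, each approximating a doubled
    exposure in which one insect's consecutive blurs overlap.
    """
    if len(frames) < 2:
        raise ValueError(f"need at least 2 frames, got {len(frames)}")
    arrays = [_as_pixels(f) for f in frames]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"frames have mismatched shapes: {sorted(shapes)}")
    return [np.maximum(a, b) for a, b in zip(arrays[:-1], arrays[1:])]


def solve_assignment(cost: np.ndarray, threshold: float = math.inf) -> Set[Tuple[int, int]]:
    """Minimum-cost one-to-one partial matching of rows to columns.

    Solves the linear sum assignment problem (Jonker-Volgenant family,
    via scipy).  Rectangular matrices are padded to square with the
    threshold cost so that leaving a detection unmatched competes fairly
    with matching it; pairs with cost above the threshold are then
    removed ("links with d_M above a specified threshold").  Retention is
    inclusive: a link at exactly the threshold survives.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.size == 0:
        return set()
    if cost.ndim != 2:
        raise ValueError("cost must be a 2-D matrix")
    if not np.all(np.isfinite(cost)) or cost.min() < 0:
        raise ValueError("costs must be finite and non-negative")
    n, m = cost.shape
    if math.isinf(threshold):
        rows, cols = linear_sum_assignment(cost)
        return set(zip(rows.tolist(), cols.tolist()))
    size = max(n, m)
    padded = np.full((size, size), float(threshold))
    padded[:n, :m] = cost
    rows, cols = linear_sum_assignment(padded)
    return {
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < n and c < m and cost[r, c] <= threshold
    }


def link_detections(
    dets_t: Sequence[Detection],
    dets_t1: Sequence[Detection],
    cfg: Optional[TrackingConfig] = None,
) -> Set[Tuple[int, int]]:
    """Link detections of successive maximum images by minimum-total d_M.

    Returns index pairs (i in dets_t, j in dets_t1).  Only polyline
    detections participate; others can never be linked.
    """
    cfg = cfg or TrackingConfig()
    it = [i for i, d in enumerate(dets_t) if d.polyline is not None]
    jt = [j for j, d in enumerate(dets_t1) if d.polyline is not None]
    if not it or not jt:
        return set()
    cost = np.empty((len(it), len(jt)))
    for a, i in enumerate(it):
        for b, j in enumerate(jt):
            cost[a, b] = matching_distance(dets_t[i].polyline, dets_t1[j].polyline)
    return {(it[a], jt[b]) for a, b in solve_assignment(cost, cfg.dm_threshold)}


def build_trajectories(
    per_pair_detections: Sequence[Sequence[Detection]],
    cfg: Optional[TrackingConfig] = None,
) -> List[Trajectory]:
    """Chain detections across all pair indices into trajectories.

    Linked detections extend the trajectory of their predecessor;
    unlinked detections start new trajectories.  Every detection ends up
    in exactly one trajectory.
    """
    cfg = cfg or TrackingConfig()
    chains: List[List[Detection]] = []
    # open_by_index[j] = chain currently ending at detection j of the last step
    open_by_index: Dict[int, List[Detection]] = {}
    prev: Sequence[Detection] = []
    for dets in per_pair_detections:
        links = link_detections(prev, dets, cfg) if prev else set()
        linked_to: Dict[int, int] = {j: i for i, j in links}
        new_open: Dict[int, List[Detection]] = {}
        for j, det in enumerate(dets):
            if j in linked_to and linked_to[j] in open_by_index:
                chain = open_by_index[linked_to[j]]
            else:
                chain = []
                chains.append(chain)
            chain.append(det)
            new_open[j] = chain
        open_by_index = new_open
        prev = dets
    return [Trajectory(c) for c in chains]


def filter_trajectories(trajectories: Sequence[Trajectory], cfg: Optional[TrackingConfig] = None) -> List[Trajectory]:
    """Drop short chains, then chains with low mean detection score."""
    cfg = cfg or TrackingConfig()
    long_enough = [t for t in trajectories if t.n_detections >= cfg.min_detections]
    return [t for t in long_enough if t.mean_score >= cfg.min_mean_score]


def roi_filter(trajectories: Sequence[Trajectory], roi: Circle) -> List[Trajectory]:
    """Keep trajectories whose polyline detections lie wholly inside the ROI.

    The circle is convex, so checking every polyline vertex (inclusive
    boundary) suffices for whole segments.
    """
    centre = np.array([roi.cx, roi.cy])
    kept = []
    for traj in trajectories:
        ok = True
        for det in traj.detections:
            poly = det.polyline
            if poly is None:
                continue
            if np.any(np.linalg.norm(poly.vertices - centre, axis=1) > roi.r):
                ok = False
                break
        if ok:
            kept.append(traj)
    return kept


def _oriented_endpoints(polylines: List[Polyline]) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Orient each chain member so successive ends flow in one direction."""
    oriented: List[Polyline] = []
    first = polylines[0]
    if len(polylines) > 1:
        nxt = polylines[1]
        # orient the first so that its end is nearer the second chain
        if point_to_polyline_distance(tuple(first.vertices[-1]), nxt) > point_to_polyline_distance(
            tuple(first.vertices[0]), nxt
        ):
            first = first.reversed()
    oriented.append(first)
    for poly in polylines[1:]:
        prev_end = oriented[-1].vertices[-1]
        d_start = np.linalg.norm(poly.vertices[0] - prev_end)
        d_end = np.linalg.norm(poly.vertices[-1] - prev_end)
        oriented.append(poly if d_start <= d_end else poly.reversed())
    return [(p.vertices[0], p.vertices[-1]) for p in oriented]


def trajectory_direction(traj: Trajectory) -> float:
    """Displacement direction of a trajectory in degrees, (-180, 180].

    Image coordinates: 0 deg points along +x (rightward), 90 deg along +y
    (down the image).  Conversion to a compass bearing requires the
    camera orientation and is left to the caller.
    """
    polylines = [d.polyline for d in traj.detections if d.polyline is not None]
    if len(polylines) < 2:
        raise ValueError("direction undefined for trajectories with < 2 polyline detections")
    endpoints = _oriented_endpoints(polylines)
    start = endpoints[0][0]
    end = endpoints[-1][1]
    angle = math.degrees(math.atan2(end[1] - start[1], end[0] - start[0]))
    if angle <= -180.0:
        angle += 360.0
    return angle


@dataclass
class TrackingResult:
    """Trajectories plus per-stage bookkeeping counts."""

    trajectories: List[Trajectory]
    n_detections: int
    n_trajectories_raw: int
    n_after_length_filter: int
    n_after_score_filter: int
    n_after_roi: int

    def __iter__(self):
        return iter(self.trajectories)

    def __len__(self) -> int:
        return len(self.trajectories)


def track_batch(frames: Sequence[Union[Frame, np.ndarray]], cfg: Optional[TrackingConfig] = None) -> TrackingResult:
    """Full pipeline: maximum images -> detection -> linking -> filters."""
    cfg = cfg or TrackingConfig()
    maxima = pairwise_maximum(frames)
    per_pair: List[List[Detection]] = []
    n_det = 0
    for t, img in enumerate(maxima):
        dets = [
            Detection(ann, ann.score if ann.score is not None else 0.0, t)
            for ann in annotate_image(img, cfg.detector)
        ]
        n_det += len(dets)
        per_pair.append(dets)
    raw = build_trajectories(per_pair, cfg)
    long_enough = [t for t in raw if t.n_detections >= cfg.min_detections]
    scored = [t for t in long_enough if t.mean_score >= cfg.min_mean_score]
    final = roi_filter(scored, cfg.roi) if cfg.roi is not None else scored
    return TrackingResult(
        trajectories=final,
        n_detections=n_det,
        n_trajectories_raw=len(raw),
        n_after_length_filter=len(long_enough),
        n_after_score_filter=len(scored),
        n_after_roi=len(final),
    )


def trajectories_to_dataframe(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Flat per-detection table: trajectory id, pair index, score, direction."""
    rows = []
    for tid, traj in enumerate(trajectories):
        try:
            direction = trajectory_direction(traj)
        except ValueError:
            direction = float("nan")
        for det in traj.detections:
            rows.append(
                {
                    "trajectory_id": tid,
                    "pair_index": det.pair_index,
                    "score": det.score,
                    "direction_deg": direction,
                    "n_detections": traj.n_detections,
                }
            )
    return pd.DataFrame(
        rows, columns=["trajectory_id", "pair_index", "score", "direction_deg", "n_detections"]
    )


def trajectories_to_via(
    trajectories: Sequence[Trajectory],
    image_names: Sequence[str],
) -> ViaProject:
    """Trajectories as a VIA project, one record per maximum image.

    ``image_names[t]`` names the maximum image with pair index t.  Each
    detection becomes a region whose attributes carry the trajectory id.
    """
    records = [ImageRecord(name, -1, []) for name in image_names]
    for tid, traj in enumerate(trajectories):
        for det in traj.detections:
            rec = records[det.pair_index]
            rec.regions.append(Annotation(det.annotation.shape, det.score))
            rec.region_extra.append({"trajectory_id": str(tid)})
    return ViaProject(records)
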