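"""Planar primitives for motion-blur annotations.

Coordinates follow the image-annotation convention used by VIA: ``x`` is
the column, ``y`` the row, the origin sits at the centre of the top-left
pixel, and sub-pixel positions are plain floats.

The central quantity here is the *matching distance* ``d_M`` between two
polylines: the second-smallest of the four distances from each polyline's
endpoints to the other polyline.  Two blurs that continue one another
(end-to-end, or overlapping along a shared path) score near zero, while
two blurs that merely cross at an angle score roughly half the shorter
blur's length.  Note that ``d_M`` is deliberately *not* a metric — two
abutting but disjoint segments have ``d_M == 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import shapely

__all__ = [
    "Point2D",
    "Polyline",
    "Circle",
    "PointMark",
    "Annotation",
    "BBox",
    "polyline_length",
    "point_to_polyline_distance",
    "points_to_polyline_distance",
    "matching_distance",
    "resample_polyline",
    "hausdorff_distance",
    "bbox_of",
    "bbox_iou",
    "min_enclosing_circle",
]

Shape = Union["Polyline", "Circle", "PointMark"]


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name}: non-finite coordinate {v!r}")


@dataclass(frozen=True)
class Point2D:
    """A sub-pixel image location (x = column, y = row)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        _require_finite("Point2D", self.x, self.y)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class Polyline:
    """An ordered open chain of >= 2 vertices, stored as an (n, 2) array.

    Column 0 is x, column 1 is y.  Consecutive duplicate vertices are
    rejected so every segment has positive length.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError(f"Polyline vertices must be (n, 2), got {v.shape}")
        if v.shape[0] < 2:
            raise ValueError("Polyline needs at least 2 vertices")
        if not np.all(np.isfinite(v)):
            raise ValueError("Polyline vertices must be finite")
        if np.any(np.all(v[1:] == v[:-1], axis=1)):
            raise ValueError("Polyline has consecutive duplicate vertices")
        v.setflags(write=False)
        object.__setattr__(self, "vertices", v)

    @classmethod
    def from_xy(cls, xs: Sequence[float], ys: Sequence[float]) -> "Polyline":
        return cls(np.column_stack([np.asarray(xs, float), np.asarray(ys, float)]))

    @property
    def xs(self) -> np.ndarray:
        return self.vertices[:, 0]

    @property
    def ys(self) -> np.ndarray:
        return self.vertices[:, 1]

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def reversed(self) -> "Polyline":
        return Polyline(self.vertices[::-1].copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Polyline):
            return NotImplemented
        return self.vertices.shape == other.vertices.shape and bool(
            np.all(self.vertices == other.vertices)
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass(frozen=True)
class Circle:
    """Enclosing-circle annotation for clipped or occluded blurs."""

    cx: float
    cy: float
    r: float

    def __post_init__(self) -> None:
        _require_finite("Circle", self.cx, self.cy, self.r)
        if self.r <= 0:
            raise ValueError(f"Circle radius must be > 0, got {self.r}")


@dataclass(frozen=True)
class PointMark:
    """Point annotation for blurs too short to trace."""

    cx: float
    cy: float

    def __post_init__(self) -> None:
        _require_finite("PointMark", self.cx, self.cy)


_KIND_OF = {Polyline: "polyline", Circle: "circle", PointMark: "point"}


@dataclass(frozen=True)
class Annotation:
    """A shape plus an optional detection confidence in [0, 1]."""

    shape: Shape
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if type(self.shape) not in _KIND_OF:
            raise TypeError(f"Unsupported shape type {type(self.shape).__name__}")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")

    @property
    def kind(self) -> str:
        return _KIND_OF[type(self.shape)]


@dataclass(frozen=True)
class BBox:
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        _require_finite("BBox", self.x_min, self.y_min, self.x_max, self.y_max)
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise ValueError("BBox min must not exceed max")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


def polyline_length(p: Polyline) -> float:
    """Total Euclidean arc length in pixels."""
    return float(np.sum(np.hypot(*(np.diff(p.vertices, axis=0).T))))


def points_to_polyline_distance(points: np.ndarray, p: Polyline) -> np.ndarray:
    """Exact minimum distance from each query point to the polyline.

    Projects every point onto every segment with the projection parameter
    clamped to [0, 1]; vectorised over a (q, 2) array of query points.
    """
    q = np.atleast_2d(np.asarray(points, dtype=float))
    a = p.vertices[:-1]          # (s, 2) segment starts
    d = np.diff(p.vertices, axis=0)  # (s, 2) segment vectors
    len2 = np.einsum("ij,ij->i", d, d)  # always > 0 (no duplicate vertices)
    # t[i, j]: projection of point i on segment j, clamped
    t = np.clip(np.einsum("ik,jk->ij", q, d) - np.einsum("jk,jk->j", a, d), 0.0, len2)
    t /= len2
    closest = a[None, :, :] + t[:, :, None] * d[None, :, :]
    dist = np.linalg.norm(q[:, None, :] - closest, axis=2)
    return dist.min(axis=1)


def point_to_polyline_distance(x: Union[Point2D, Sequence[float]], p: Polyline) -> float:
    """Euclidean distance from a point to the closest point on a polyline."""
    if isinstance(x, Point2D):
        x = (x.x, x.y)
    return float(points_to_polyline_distance(np.asarray(x, float)[None, :], p)[0])


def matching_distance(pa: Polyline, pb: Polyline) -> float:
    """Matching distance d_M between two polylines.

    The second-smallest element of the multiset
    ``{d(a_first, Pb), d(a_last, Pb), d(b_first, Pa), d(b_last, Pa)}``.
    Symmetric in its arguments and zero for identical, overlapping or
    end-to-end abutting polylines.
    """
    da = points_to_polyline_distance(pa.vertices[[0, -1]], pb)
    db = points_to_polyline_distance(pb.vertices[[0, -1]], pa)
    four = np.sort(np.concatenate([da, db]))
    return float(four[1])


def resample_polyline(p: Polyline, step: float = 0.5) -> np.ndarray:
    """Points along the polyline at <= ``step`` px arc-length spacing.

    Includes both endpoints and every original vertex.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    pieces = [p.vertices[:1]]
    for a, b in zip(p.vertices[:-1], p.vertices[1:]):
        seg = np.hypot(*(b - a))
        n = max(1, int(math.ceil(seg / step)))
        t = np.arange(1, n + 1, dtype=float)[:, None] / n
        pieces.append(a[None, :] + t * (b - a)[None, :])
    return np.concatenate(pieces, axis=0)


def hausdorff_distance(pa: Polyline, pb: Polyline, step: float = 0.5) -> float:
    """Symmetric Hausdorff distance between two polylines.

    Each polyline is resampled at <= ``step`` px arc-length spacing and the
    directed distances are evaluated exactly from the samples to the other
    polyline, so the result is accurate to within ``step`` of the true
    polyline Hausdorff distance (and exact whenever the supremum is
    attained at a vertex, as it is for straight segments).
    """
    d_ab = points_to_polyline_distance(resample_polyline(pa, step), pb).max()
    d_ba = points_to_polyline_distance(resample_polyline(pb, step), pa).max()
    return float(max(d_ab, d_ba))


def bbox_of(obj: Union[Annotation, Shape]) -> BBox:
    """Tight axis-aligned bounding box of an annotation or bare shape."""
    shape = obj.shape if isinstance(obj, Annotation) else obj
    if isinstance(shape, Polyline):
        xs, ys = shape.xs, shape.ys
        return BBox(float(xs.min()), float(ys.min()), float(xs.max()), float(ys.max()))
    if isinstance(shape, Circle):
        return BBox(shape.cx - shape.r, shape.cy - shape.r, shape.cx + shape.r, shape.cy + shape.r)
    if isinstance(shape, PointMark):
        return BBox(shape.cx, shape.cy, shape.cx, shape.cy)
    raise TypeError(f"Unsupported shape type {type(shape).__name__}")


def bbox_iou(b1: BBox, b2: BBox) -> float:
    """Intersection over union of two boxes; 0 when both are degenerate."""
    ix = min(b1.x_max, b2.x_max) - max(b1.x_min, b2.x_min)
    iy = min(b1.y_max, b2.y_max) - max(b1.y_min, b2.y_min)
    inter = max(ix, 0.0) * max(iy, 0.0)
    union = b1.area + b2.area - inter
    if union <= 0.0:
        return 0.0
    return float(inter / union)


def min_enclosing_circle(points: Iterable[Sequence[float]]) -> Circle:
    """Minimum enclosing circle of a point set.

    Delegates to shapely's minimum bounding circle; the radius is padded by
    nothing — callers wanting to enclose finite-width blobs should inflate
    it themselves.
    """
    pts = np.atleast_2d(np.asarray(list(points) if not isinstance(points, np.ndarray) else points, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("min_enclosing_circle of empty point set")
    mp = shapely.MultiPoint(pts)
    r = float(shapely.minimum_bounding_radius(mp))
    centre = shapely.minimum_bounding_circle(mp).centroid
    return Circle(float(centre.x), float(centre.y), max(r, 1e-9))
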