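"""Classical motion-blur streak detector.

Flying insects photographed at night under an infra-red flash leave
bright, roughly curve-shaped streaks on a dark and fairly uniform sky
background.  This detector exploits exactly that structure:

1. threshold at ``background median + k * MAD`` (robust to the sparse
   bright pixels the streaks themselves contribute),
2. close small gaps morphologically and take 8-connected components,
3. fit each component with a polynomial in its principal-axis frame to
   recover a polyline along the blur path — insect flight within a
   single exposure is well modelled by low-order curves, and a 2nd-order
   polynomial is the default,
4. fall back to an enclosing circle for blurs clipped by the frame edge
   and to a point mark for blurs too short to trace.

The detector is deterministic and exposes the same contract a learned
segmentation backend would (masks in, scored annotations out), so one
can be slotted in without touching downstream tracking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Union

import numpy as np
from pydantic import BaseModel, Field, model_validator
from skimage import measure, morphology

from .geometry import Annotation, Circle, PointMark, Polyline, bbox_of, min_enclosing_circle, polyline_length

__all__ = [
    "Frame",
    "StreakMask",
    "DetectorParams",
    "DegenerateMaskError",
    "to_grayscale",
    "segment_streaks",
    "detection_score",
    "mask_to_polyline",
    "classify_and_annotate",
    "annotate_image",
]


class DegenerateMaskError(ValueError):
    """Mask extent too small along its principal axis to fit a curve."""


@dataclass(frozen=True)
class Frame:
    """A grayscale frame: H x W intensities in [0, 255] plus an index."""

    pixels: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"Frame must be 2-D grayscale, got shape {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError(f"Frame must be at least 8x8, got {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("Frame intensities must lie in [0, 255]")
        if self.index < 0:
            raise ValueError("Frame index must be >= 0")
        object.__setattr__(self, "pixels", px)


def _as_pixels(frame: Union[Frame, np.ndarray]) -> np.ndarray:
    return frame.pixels if isinstance(frame, Frame) else np.asarray(frame)


def to_grayscale(image: np.ndarray, method: str = "max") -> np.ndarray:
    """Collapse an RGB(A) image to grayscale.

    Default is the channel maximum: streaks are near-white under IR
    flash, so the max preserves them best.  ``method="luminance"`` uses
    the usual Rec.601 weights instead.
    """
    if image.ndim == 2:
        return image
    rgb = image[..., :3].astype(float)
    if method == "max":
        return rgb.max(axis=-1)
    if method == "luminance":
        return rgb @ np.array([0.299, 0.587, 0.114])
    raise ValueError(f"unknown grayscale method {method!r}")


@dataclass(frozen=True)
class StreakMask:
    """One connected component of above-threshold pixels.

    ``pixels`` is an (n, 2) integer array of (row, col) coordinates.
    """

    pixels: np.ndarray
    mean_intensity: float
    touches_border: bool

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.size == 0:
            raise ValueError("StreakMask must be non-empty")
        object.__setattr__(self, "pixels", px)

    @property
    def area(self) -> int:
        return self.pixels.shape[0]

    @property
    def centroid_xy(self) -> tuple:
        return (float(self.pixels[:, 1].mean()), float(self.pixels[:, 0].mean()))


class DetectorParams(BaseModel):
    """Tunables of the classical detector (all lengths in pixels)."""

    threshold_k: float = Field(8.0, gt=0, description="MAD multiples above background median")
    min_area: int = Field(20, gt=0)
    closing_radius: int = Field(1, gt=0)
    border_margin: int = Field(2, gt=0)
    min_polyline_length: float = Field(10.0, gt=0)
    polyline_order: int = Field(2, ge=1)
    vertices_per_polyline: int = Field(10, ge=2)

    @model_validator(mode="after")
    def _check_vertices(self) -> "DetectorParams":
        if self.vertices_per_polyline < self.polyline_order + 1:
            raise ValueError("vertices_per_polyline must be >= polyline_order + 1")
        return self


def background_stats(frame: Union[Frame, np.ndarray]) -> tuple:
    """Per-frame (median, MAD) of pixel intensities; robust to sparse streaks."""
    px = _as_pixels(frame).astype(float)
    med = float(np.median(px))
    mad = float(np.median(np.abs(px - med)))
    return med, mad


def segment_streaks(frame: Union[Frame, np.ndarray], params: Optional[DetectorParams] = None) -> List[StreakMask]:
    """Extract candidate streak masks from a frame.

    Binarise at ``median + threshold_k * MAD``, close gaps, label
    8-connected components and drop those below ``min_area``.  A uniform
    frame (zero MAD) yields no detections.
    """
    params = params or DetectorParams()
    px = _as_pixels(frame).astype(float)
    med, mad = background_stats(px)
    above = px > med + params.threshold_k * mad
    if not above.any():
        return []
    closed = morphology.closing(above, morphology.disk(params.closing_radius))
    labels = measure.label(closed, connectivity=2)
    h, w = px.shape
    m = params.border_margin
    masks: List[StreakMask] = []
    for region in measure.regionprops(labels):
        if region.area < params.min_area:
            continue
        coords = region.coords  # (n, 2) row, col
        touches = bool(
            (coords[:, 0] < m).any()
            or (coords[:, 0] >= h - m).any()
            or (coords[:, 1] < m).any()
            or (coords[:, 1] >= w - m).any()
        )
        # intensity statistic over the genuinely bright pixels only
        # (closing is for connectivity; the gap pixels it fills sit at
        # background level), summarised by the median so the streak-core
        # contrast is not diluted by the anti-aliased fringe
        bright = above[coords[:, 0], coords[:, 1]]
        sel = coords[bright] if bright.any() else coords
        mean_on = float(np.median(px[sel[:, 0], sel[:, 1]]))
        masks.append(StreakMask(coords, mean_on, touches))
    return masks


def detection_score(mask: StreakMask, frame: Union[Frame, np.ndarray]) -> float:
    """Contrast-based confidence: (mean_on - bg median) / (255 - bg median)."""
    med, _ = background_stats(frame)
    if med >= 255.0:
        return 0.0
    return float(np.clip((mask.mean_intensity - med) / (255.0 - med), 0.0, 1.0))


def mask_to_polyline(mask: StreakMask, order: int = 2, n_vertices: int = 10) -> Polyline:
    """Fit a polyline along a mask via polynomial regression.

    Pixel coordinates are rotated into the principal-axis frame (the
    direction of largest coordinate variance; isotropic ties break toward
    the x-axis), a least-squares polynomial ``v = sum c_k u^k`` is fitted,
    evaluated at ``n_vertices`` equally spaced abscissae, and rotated
    back.  Masks with too few distinct abscissae for the requested order
    fall back to a straight-line fit; masks with essentially no extent
    raise :class:`DegenerateMaskError`.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if n_vertices < max(2, order + 1):
        raise ValueError("n_vertices must be >= max(2, order + 1)")
    xy = mask.pixels[:, ::-1].astype(float)  # (n, 2) as (x, y)
    centre = xy.mean(axis=0)
    centred = xy - centre
    cov = np.cov(centred.T) if centred.shape[0] > 1 else np.zeros((2, 2))
    evals, evecs = np.linalg.eigh(cov)
    if np.isclose(evals[0], evals[1]):
        axis = np.array([1.0, 0.0])  # isotropic: default to the x-axis
    else:
        axis = evecs[:, int(np.argmax(evals))]
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis  # deterministic sign
    normal = np.array([-axis[1], axis[0]])
    u = centred @ axis
    v = centred @ normal

    distinct = np.unique(np.round(u, 6))
    if distinct.size < 2 or (u.max() - u.min()) < 1.0:
        raise DegenerateMaskError("mask has (sub-)pixel extent along its principal axis")
    eff_order = order if distinct.size >= order + 1 else 1
    coeffs = np.polyfit(u, v, eff_order)
    u_eval = np.linspace(u.min(), u.max(), n_vertices)
    v_eval = np.polyval(coeffs, u_eval)
    pts = centre[None, :] + u_eval[:, None] * axis[None, :] + v_eval[:, None] * normal[None, :]
    return Polyline(pts)


def classify_and_annotate(
    mask: StreakMask,
    frame: Union[Frame, np.ndarray],
    params: Optional[DetectorParams] = None,
) -> Annotation:
    """Turn one mask into a scored polyline / circle / point annotation.

    Border-touching blurs (partially out of frame) get the minimum
    enclosing circle; interior blurs get a fitted polyline unless they
    are too short to trace, in which case a point mark at the centroid.
    """
    params = params or DetectorParams()
    score = detection_score(mask, frame)
    if mask.touches_border:
        return Annotation(min_enclosing_circle(mask.pixels[:, ::-1]), score)
    try:
        poly = mask_to_polyline(mask, params.polyline_order, params.vertices_per_polyline)
    except DegenerateMaskError:
        cx, cy = mask.centroid_xy
        return Annotation(PointMark(cx, cy), score)
    if polyline_length(poly) < params.min_polyline_length:
        cx, cy = mask.centroid_xy
        return Annotation(PointMark(cx, cy), score)
    return Annotation(poly, score)


def annotate_image(frame: Union[Frame, np.ndarray], params: Optional[DetectorParams] = None) -> List[Annotation]:
    """Detect and annotate every streak in a frame.

    Deterministic: annotations are sorted by bounding-box (x_min, y_min).
    """
    params = params or DetectorParams()
    annotations = [classify_and_annotate(m, frame, params) for m in segment_streaks(frame, params)]
    annotations.sort(key=lambda a: (bbox_of(a).x_min, bbox_of(a).y_min))
    return annotations
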