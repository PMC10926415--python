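"""Read and write VIA (VGG Image Annotator) version-2 project files.

The project JSON is the interchange format between manual annotation in
VIA and the automatic annotator/tracker here, so reading followed by
writing must be an exact identity: coordinates survive bit-for-bit
(JSON shortest-repr floats) and detection scores are carried as decimal
strings under the ``region_attributes`` key ``"score"``.

Both on-disk dialects are accepted: a full project document (with
``_via_img_metadata``) and the bare image-metadata mapping that VIA's
"export annotations" produces.  Writing always emits the full document.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Union

from PIL import Image

from .geometry import Annotation, Circle, PointMark, Polyline

logger = logging.getLogger(__name__)

__all__ = [
    "ImageRecord",
    "ViaProject",
    "ViaParseError",
    "ViaValidationError",
    "MissingExposureError",
    "ExposureInfo",
    "read_via_project",
    "load_via_project",
    "write_via_project",
    "save_via_project",
    "exposure_time_for",
]

#: EXIF tag id of ExposureTime
_EXIF_EXPOSURE_TIME = 0x829A


class ViaParseError(ValueError):
    """The document is not well-formed JSON."""


class ViaValidationError(ValueError):
    """A region fails the VIA v2 shape schema."""


class MissingExposureError(LookupError):
    """No exposure time available from EXIF or configuration."""


@dataclass
class ImageRecord:
    filename: str
    file_size: int = -1
    regions: List[Annotation] = field(default_factory=list)
    exposure_time: Optional[float] = None
    #: extra region_attributes (beyond "score") per region, parallel to regions
    region_extra: Optional[List[dict]] = None

    def __post_init__(self) -> None:
        if not self.filename:
            raise ValueError("ImageRecord.filename must be non-empty")
        if self.exposure_time is not None and self.exposure_time <= 0:
            raise ValueError("exposure_time must be > 0 when present")
        if self.region_extra is None:
            self.region_extra = [{} for _ in self.regions]
        if len(self.region_extra) != len(self.regions):
            raise ValueError("region_extra must parallel regions")

    @property
    def key(self) -> str:
        """VIA's image key: filename concatenated with file size."""
        return f"{self.filename}{self.file_size}"


@dataclass
class ViaProject:
    records: List[ImageRecord] = field(default_factory=list)
    #: number of regions with unrecognised shapes skipped on read
    skipped_regions: int = 0

    def __post_init__(self) -> None:
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("ViaProject image keys must be unique")

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _region_to_annotation(region: dict, filename: str, index: int) -> Optional[Annotation]:
    """Translate one VIA region dict; None means 'skip (unknown shape)'."""

    def fail(msg: str) -> ViaValidationError:
        return ViaValidationError(f"{filename} region {index}: {msg}")

    shape_attrs = region.get("shape_attributes", {})
    name = shape_attrs.get("name")
    if name == "polyline":
        xs = shape_attrs.get("all_points_x")
        ys = shape_attrs.get("all_points_y")
        if xs is None or ys is None:
            raise fail("polyline missing all_points_x/all_points_y")
        if len(xs) != len(ys):
            raise fail(f"coordinate lists differ in length ({len(xs)} vs {len(ys)})")
        if len(xs) < 2:
            raise fail(f"polyline needs >= 2 points, got {len(xs)}")
        try:
            shape = Polyline.from_xy(xs, ys)
        except ValueError as e:
            raise fail(str(e)) from e
    elif name == "circle":
        try:
            shape = Circle(float(shape_attrs["cx"]), float(shape_attrs["cy"]), float(shape_attrs["r"]))
        except (KeyError, ValueError) as e:
            raise fail(f"bad circle: {e}") from e
    elif name == "point":
        try:
            shape = PointMark(float(shape_attrs["cx"]), float(shape_attrs["cy"]))
        except (KeyError, ValueError) as e:
            raise fail(f"bad point: {e}") from e
    else:
        return None

    score = None
    raw = region.get("region_attributes", {}).get("score")
    if raw is not None and raw != "":
        try:
            score = float(raw)
        except (TypeError, ValueError) as e:
            raise fail(f"score {raw!r} is not a number") from e
        if not (0.0 <= score <= 1.0):
            raise fail(f"score {score} outside [0, 1]")
    return Annotation(shape, score)


def read_via_project(document: str) -> ViaProject:
    """Parse VIA v2 JSON text into a :class:`ViaProject`.

    Unknown region shapes (``rect``, ``ellipse``, ...) are skipped with a
    warning and counted in ``ViaProject.skipped_regions``; malformed
    polylines raise :class:`ViaValidationError` naming the image and
    region index.
    """
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as e:
        raise ViaParseError(f"malformed VIA JSON at byte offset {e.pos}: {e.msg}") from e
    if not isinstance(doc, dict):
        raise ViaParseError("VIA document must be a JSON object")
    metadata = doc.get("_via_img_metadata", doc)
    if not isinstance(metadata, dict):
        raise ViaParseError("_via_img_metadata must be a JSON object")

    records: List[ImageRecord] = []
    skipped = 0
    for key, entry in metadata.items():
        filename = entry.get("filename") or key
        size = int(entry.get("size", -1))
        regions: List[Annotation] = []
        extras: List[dict] = []
        for i, region in enumerate(entry.get("regions", [])):
            ann = _region_to_annotation(region, filename, i)
            if ann is None:
                skipped += 1
                logger.warning(
                    "skipping region %d of %s: unknown shape %r",
                    i, filename, region.get("shape_attributes", {}).get("name"),
                )
            else:
                regions.append(ann)
                extras.append(
                    {k: v for k, v in region.get("region_attributes", {}).items() if k != "score"}
                )
        exposure = None
        raw_exp = entry.get("file_attributes", {}).get("exposure_time")
        if raw_exp not in (None, ""):
            exposure = float(raw_exp)
        records.append(ImageRecord(filename, size, regions, exposure, extras))
    return ViaProject(records, skipped_regions=skipped)


def load_via_project(path: Union[str, Path]) -> ViaProject:
    """Read a VIA project from disk."""
    return read_via_project(Path(path).read_text())


def _annotation_to_region(ann: Annotation, extra: Optional[dict] = None) -> dict:
    shape = ann.shape
    if isinstance(shape, Polyline):
        shape_attrs = {
            "name": "polyline",
            "all_points_x": [float(x) for x in shape.xs],
            "all_points_y": [float(y) for y in shape.ys],
        }
    elif isinstance(shape, Circle):
        shape_attrs = {"name": "circle", "cx": shape.cx, "cy": shape.cy, "r": shape.r}
    elif isinstance(shape, PointMark):
        shape_attrs = {"name": "point", "cx": shape.cx, "cy": shape.cy}
    else:  # pragma: no cover - Annotation already validates
        raise TypeError(type(shape).__name__)
    region_attrs = dict(extra or {})
    if ann.score is not None:
        region_attrs["score"] = repr(ann.score)
    return {"shape_attributes": shape_attrs, "region_attributes": region_attrs}


def write_via_project(project: ViaProject) -> str:
    """Serialise to the full VIA v2 project-document dialect."""
    metadata = {}
    for rec in project.records:
        file_attrs = {}
        if rec.exposure_time is not None:
            file_attrs["exposure_time"] = repr(rec.exposure_time)
        metadata[rec.key] = {
            "filename": rec.filename,
            "size": rec.file_size,
            "regions": [
                _annotation_to_region(a, e) for a, e in zip(rec.regions, rec.region_extra)
            ],
            "file_attributes": file_attrs,
        }
    doc = {
        "_via_settings": {
            "ui": {},
            "core": {"buffer_size": 18, "filepath": {}, "default_filepath": ""},
            "project": {"name": "streaktrack"},
        },
        "_via_img_metadata": metadata,
        "_via_attributes": {
            "region": {"score": {"type": "text", "description": "detection confidence", "default_value": ""}},
            "file": {"exposure_time": {"type": "text", "description": "exposure in seconds", "default_value": ""}},
        },
    }
    return json.dumps(doc, indent=1)


def save_via_project(project: ViaProject, path: Union[str, Path]) -> None:
    Path(path).write_text(write_via_project(project))


@dataclass(frozen=True)
class ExposureInfo:
    seconds: float
    source: str  # "exif" | "record" | "config"


def exposure_time_for(
    source: Union[str, Path, ImageRecord],
    default: Optional[float] = None,
) -> ExposureInfo:
    """Resolve the exposure time for an image.

    Checks, in order: a record's own ``exposure_time``; the EXIF
    ExposureTime tag of an image file; the configured default.  Wingbeat
    estimation cannot proceed without it, so the miss is an error.
    """
    if isinstance(source, ImageRecord):
        if source.exposure_time is not None:
            return ExposureInfo(float(source.exposure_time), "record")
    else:
        path = Path(source)
        if path.is_file():
            try:
                with Image.open(path) as img:
                    raw = img.getexif().get(_EXIF_EXPOSURE_TIME)
            except OSError:
                raw = None
            if raw is not None:
                # ExposureTime is a rational: IFDRational, (num, den), or float
                if isinstance(raw, tuple) and len(raw) == 2:
                    seconds = raw[0] / raw[1] if raw[1] else 0.0
                else:
                    seconds = float(raw)
                if seconds > 0:
                    return ExposureInfo(seconds, "exif")
    if default is not None:
        if default <= 0:
            raise ValueError("default exposure must be > 0")
        return ExposureInfo(float(default), "config")
    name = source.filename if isinstance(source, ImageRecord) else str(source)
    raise MissingExposureError(
        f"no exposure time for {name}: not in EXIF/record and no configured default"
    )
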