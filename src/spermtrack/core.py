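"""Shared geometry, calibration, and file-format primitives.

Coordinate conventions used throughout the package:

* pixel coordinates are continuous, 0-based, origin at the top-left corner,
  x increasing rightward and y increasing downward;
* bounding boxes are stored as corners ``(x_min, y_min, x_max, y_max)`` and
  are half-open in the continuous sense, so
  ``area = (x_max - x_min) * (y_max - y_min)``;
* physical positions are in micrometres, obtained from pixels through a
  :class:`CalibrationProfile`.

The YOLO text format (normalized ``class cx cy w h`` per line, one file per
frame) and a flat track CSV are the only on-disk interchange formats.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BoundingBox",
    "Detection",
    "AnnotatedBox",
    "FrameAnnotation",
    "CalibrationProfile",
    "VideoSequence",
    "TrackRow",
    "iou",
    "to_microns",
    "to_pixels",
    "read_yolo_annotations",
    "write_yolo_annotations",
    "read_track_table",
    "write_track_table",
    "read_image_sequence",
    "write_image_sequence",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in continuous pixel coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if self.x_max < self.x_min or self.y_max < self.y_min:
            raise ValueError(
                f"invalid box: ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def translate(self, dx: float, dy: float) -> "BoundingBox":
        return BoundingBox(self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy)

    def union_extent(self, other: "BoundingBox") -> "BoundingBox":
        """Smallest box enclosing both boxes."""
        return BoundingBox(
            min(self.x_min, other.x_min),
            min(self.y_min, other.y_min),
            max(self.x_max, other.x_max),
            max(self.y_max, other.y_max),
        )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes.

    Raises
    ------
    ValueError
        If both boxes are degenerate (zero area): the ratio is then 0/0 and
        silently returning 0 would hide broken annotations.
    """
    if a.area == 0 and b.area == 0:
        raise ValueError("IoU undefined: both boxes have zero area")
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    inter = max(ix, 0.0) * max(iy, 0.0)
    union = a.area + b.area - inter
    return inter / union


@dataclass
class Detection:
    """One detector output: a box, a confidence, and (optionally) the head
    point and head-neck orientation that downstream motility analysis uses."""

    box: BoundingBox
    confidence: float
    head: tuple[float, float] | None = None
    orientation: float | None = None  # degrees in [0, 180)

    # margin (px) by which the head point may fall outside the box
    HEAD_MARGIN: float = field(default=2.0, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        if self.orientation is not None and not 0.0 <= self.orientation < 180.0:
            raise ValueError(f"orientation {self.orientation} outside [0, 180)")
        if self.head is not None:
            hx, hy = self.head
            m = self.HEAD_MARGIN
            if not (
                self.box.x_min - m <= hx <= self.box.x_max + m
                and self.box.y_min - m <= hy <= self.box.y_max + m
            ):
                raise ValueError("head point lies outside the (margin-expanded) box")


@dataclass
class AnnotatedBox:
    """Ground-truth box, optionally carrying a track identity."""

    box: BoundingBox
    track_id: int | None = None
    class_id: int = 0
    partially_out_of_frame: bool = False


@dataclass
class FrameAnnotation:
    frame_index: int
    boxes: list[AnnotatedBox] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")


@dataclass(frozen=True)
class CalibrationProfile:
    """Pixel-to-physical calibration.

    The defaults correspond to a 10x objective imaged at roughly
    0.14 um/pixel and a 10 frames/s acquisition rate.
    """

    microns_per_pixel: float = 0.14
    frames_per_second: float = 10.0

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0 or self.frames_per_second <= 0:
            raise ValueError("calibration values must be strictly positive")


def to_microns(point: Sequence[float] | np.ndarray, cal: CalibrationProfile) -> np.ndarray:
    """Convert a pixel point (or array of points) to micrometres."""
    return np.asarray(point, dtype=float) * cal.microns_per_pixel


def to_pixels(point: Sequence[float] | np.ndarray, cal: CalibrationProfile) -> np.ndarray:
    return np.asarray(point, dtype=float) / cal.microns_per_pixel


@dataclass
class VideoSequence:
    """Ordered grayscale frames of identical shape plus their calibration."""

    frames: list[np.ndarray]
    calibration: CalibrationProfile = field(default_factory=CalibrationProfile)

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("a VideoSequence needs at least one frame")
        shape = self.frames[0].shape
        for f in self.frames:
            if f.ndim != 2:
                raise ValueError("frames must be 2-D grayscale")
            if f.shape != shape:
                raise ValueError("all frames must share the same shape")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def times(self) -> np.ndarray:
        """Frame timestamps in seconds."""
        return np.arange(len(self.frames)) / self.calibration.frames_per_second


# ---------------------------------------------------------------------------
# YOLO annotation files


def read_yolo_annotations(
    path: str | Path,
    image_width: int,
    image_height: int,
    frame_index: int = 0,
) -> FrameAnnotation:
    """Read one YOLO-format annotation file.

    Each non-empty line is ``class cx cy w h`` with center/size normalized to
    [0, 1]; boxes are converted to absolute corner coordinates.
    """
    boxes: list[AnnotatedBox] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            try:
                cls = int(parts[0])
                cx, cy, w, h = (float(p) for p in parts[1:])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed number: {exc}") from None
            for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{path}:{lineno}: {name}={v} outside [0, 1]")
            box = BoundingBox(
                (cx - w / 2) * image_width,
                (cy - h / 2) * image_height,
                (cx + w / 2) * image_width,
                (cy + h / 2) * image_height,
            )
            boxes.append(AnnotatedBox(box=box, class_id=cls))
    return FrameAnnotation(frame_index=frame_index, boxes=boxes)


def write_yolo_annotations(
    ann: FrameAnnotation,
    image_width: int,
    image_height: int,
    path: str | Path,
) -> None:
    """Write a YOLO-format annotation file (inverse of :func:`read_yolo_annotations`).

    Boxes exceeding the image bounds are clipped with a logged warning; a
    negative-area box is an error (it cannot be represented).
    """
    lines = []
    for ab in ann.boxes:
        b = ab.box
        if b.area < 0:  # unreachable through BoundingBox, guards raw tuples
            raise ValueError("negative-area box cannot be written")
        cx_min, cy_min = max(b.x_min, 0.0), max(b.y_min, 0.0)
        cx_max, cy_max = min(b.x_max, image_width), min(b.y_max, image_height)
        if (cx_min, cy_min, cx_max, cy_max) != b.as_tuple():
            logger.warning("clipping box %s to image bounds %dx%d", b, image_width, image_height)
            b = BoundingBox(cx_min, cy_min, max(cx_max, cx_min), max(cy_max, cy_min))
        cx = 0.5 * (b.x_min + b.x_max) / image_width
        cy = 0.5 * (b.y_min + b.y_max) / image_height
        w = b.width / image_width
        h = b.height / image_height
        lines.append(f"{ab.class_id} {cx:.10g} {cy:.10g} {w:.10g} {h:.10g}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Track tables

TRACK_COLUMNS = ["frame", "id", "x_min", "y_min", "x_max", "y_max", "conf", "head_x", "head_y"]


@dataclass
class TrackRow:
    frame: int
    track_id: int
    box: BoundingBox
    confidence: float = 1.0
    head: tuple[float, float] | None = None
    observed: bool = True


def write_track_table(rows: Iterable[TrackRow], path: str | Path) -> None:
    records = []
    for r in rows:
        hx, hy = (r.head if r.head is not None else (np.nan, np.nan))
        records.append(
            {
                "frame": r.frame,
                "id": r.track_id,
                "x_min": r.box.x_min,
                "y_min": r.box.y_min,
                "x_max": r.box.x_max,
                "y_max": r.box.y_max,
                "conf": r.confidence,
                "head_x": hx,
                "head_y": hy,
                "observed": int(r.observed),
            }
        )
    df = pd.DataFrame.from_records(records, columns=TRACK_COLUMNS + ["observed"])
    df.to_csv(path, index=False)


def read_track_table(path: str | Path) -> dict[int, list[TrackRow]]:
    """Read a track CSV, grouped by track id and sorted by frame.

    Raises on duplicate (frame, id) pairs: a track can occupy only one box
    per frame.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=["frame", "id"])
    if dup.any():
        pair = df.loc[dup.idxmax(), ["frame", "id"]].tolist()
        raise ValueError(f"{path}: duplicate (frame, id) entry {tuple(pair)}")
    has_obs = "observed" in df.columns
    tracks: dict[int, list[TrackRow]] = {}
    for _, row in df.sort_values(["id", "frame"]).iterrows():
        head = None
        if np.isfinite(row["head_x"]) and np.isfinite(row["head_y"]):
            head = (float(row["head_x"]), float(row["head_y"]))
        tr = TrackRow(
            frame=int(row["frame"]),
            track_id=int(row["id"]),
            box=BoundingBox(row["x_min"], row["y_min"], row["x_max"], row["y_max"]),
            confidence=float(row["conf"]),
            head=head,
            observed=bool(row["observed"]) if has_obs else True,
        )
        tracks.setdefault(tr.track_id, []).append(tr)
    return tracks


# ---------------------------------------------------------------------------
# Image sequences

_FRAME_RE = re.compile(r"(\d+)\.(png|tif|tiff)$", re.IGNORECASE)


def read_image_sequence(
    directory: str | Path, calibration: CalibrationProfile | None = None
) -> VideoSequence:
    """Read zero-padded numbered PNG/TIFF files from a directory, in numeric order."""
    directory = Path(directory)
    entries = []
    for name in os.listdir(directory):
        m = _FRAME_RE.search(name)
        if m:
            entries.append((int(m.group(1)), name))
    if not entries:
        raise FileNotFoundError(f"no numbered PNG/TIFF frames found in {directory}")
    entries.sort()
    frames = []
    for _, name in entries:
        img = np.asarray(iio.imread(directory / name))
        if img.ndim == 3:  # collapse accidental RGB to grayscale
            img = img[..., :3].mean(axis=2).astype(img.dtype)
        frames.append(img)
    return VideoSequence(frames=frames, calibration=calibration or CalibrationProfile())


def write_image_sequence(seq: VideoSequence | list[np.ndarray], directory: str | Path,
                         prefix: str = "frame_") -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = seq.frames if isinstance(seq, VideoSequence) else seq
    paths = []
    for k, frame in enumerate(frames):
        p = directory / f"{prefix}{k:05d}.png"
        iio.imwrite(p, np.asarray(frame))
        paths.append(p)
    return paths
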