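"""Frame, detection and track-file I/O plus lightweight preprocessing.

Coordinate conventions: 0-based pixels, x rightward, y downward; boxes are
``(x, y, w, h)`` with half-open extent ``[x, x+w) x [y, y+h)``. Track files
use the MOTChallenge CSV dialect, which is 1-based; conversion happens at
the file boundary.

Overhead barn footage is typically recorded at 25-30 fps but tracked at
1 fps — cows move slowly and the appearance model needs temporally spread
samples — so the first preprocessing step is frame-rate subsampling,
optionally followed by a region-of-interest crop that keeps only the pen.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .masks import mask_bbox, mask_centroid, polygon_to_mask, rle_decode

logger = logging.getLogger(__name__)

__all__ = [
    "FrameSource",
    "Detection",
    "RoI",
    "subsample_frames",
    "apply_roi",
    "read_detections",
    "write_tracks",
    "read_tracks",
    "load_frames",
]

MOT_COLUMNS = [
    "frame", "id", "bb_left", "bb_top", "bb_width", "bb_height",
    "conf", "x", "y", "z",
]


class InvalidConfigError(ValueError):
    """Raised for contradictory preprocessing parameters."""


@dataclass
class FrameSource:
    """An ordered, constant-resolution image sequence with its frame rate."""

    frames: Sequence[np.ndarray]
    fps: float = 1.0

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    def timestamp_s(self, frame_index: int) -> float:
        return frame_index / self.fps


@dataclass
class Detection:
    """One segmented object in one frame.

    The centroid is the mask gravity center (mean of foreground pixel
    coordinates), not the bbox center.
    """

    frame_index: int
    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]
    score: float = 1.0

    @classmethod
    def from_mask(cls, frame_index: int, mask: np.ndarray, score: float = 1.0
                  ) -> "Detection":
        return cls(
            frame_index=frame_index,
            mask=np.asarray(mask, dtype=bool),
            bbox=mask_bbox(mask),
            centroid=mask_centroid(mask),
            score=float(score),
        )


@dataclass
class RoI:
    """Region of interest: a rectangle (x, y, w, h) or a polygon."""

    rect: tuple[int, int, int, int] | None = None
    polygon: np.ndarray | None = field(default=None)

    def __post_init__(self):
        if (self.rect is None) == (self.polygon is None):
            raise InvalidConfigError("RoI needs exactly one of rect, polygon")
        if self.polygon is not None:
            self.polygon = np.asarray(self.polygon, dtype=float).reshape(-1, 2)

    def bounding_rect(self) -> tuple[int, int, int, int]:
        if self.rect is not None:
            return self.rect
        x0 = int(np.floor(self.polygon[:, 0].min()))
        y0 = int(np.floor(self.polygon[:, 1].min()))
        x1 = int(np.ceil(self.polygon[:, 0].max()))
        y1 = int(np.ceil(self.polygon[:, 1].max()))
        return x0, y0, x1 - x0, y1 - y0


def subsample_frames(source: FrameSource, source_fps: float,
                     target_fps: float) -> FrameSource:
    """Keep every ``round(source_fps / target_fps)``-th frame from frame 0.

    A 30 fps barn recording subsampled to the 1 fps working rate keeps
    frames 0, 30, 60, ...; indices are renumbered from 0.
    """
    if target_fps <= 0 or source_fps <= 0:
        raise InvalidConfigError("frame rates must be positive")
    if target_fps > source_fps:
        raise InvalidConfigError(
            f"target_fps {target_fps} exceeds source_fps {source_fps}")
    stride = int(round(source_fps / target_fps))
    return FrameSource(frames=list(source.frames[::stride]), fps=target_fps)


def apply_roi(frame: np.ndarray, roi: RoI) -> np.ndarray:
    """Crop a frame to the RoI's bounding rectangle.

    For a polygonal RoI, pixels of the crop outside the polygon are zeroed.
    """
    h, w = frame.shape[:2]
    x, y, rw, rh = roi.bounding_rect()
    if rw <= 0 or rh <= 0:
        raise InvalidConfigError("RoI has non-positive area")
    x0, y0 = max(x, 0), max(y, 0)
    x1, y1 = min(x + rw, w), min(y + rh, h)
    if x1 <= x0 or y1 <= y0:
        raise InvalidConfigError("RoI does not intersect the frame")
    crop = np.array(frame[y0:y1, x0:x1])
    if roi.polygon is not None:
        shifted = roi.polygon - np.array([x0, y0], dtype=float)
        inside = polygon_to_mask(shifted, crop.shape[:2])
        crop[~inside] = 0
    return crop


def _detection_from_segmentation(frame_index: int, seg, shape, score: float,
                                 ) -> Detection | None:
    if isinstance(seg, dict):  # RLE
        mask = rle_decode(seg)
    else:  # polygon(s): list of flat coordinate lists, or one flat list
        if seg and isinstance(seg[0], (int, float)):
            seg = [seg]
        if shape is None:
            raise ValueError("polygon segmentation needs an image size")
        mask = np.zeros(shape, dtype=bool)
        for ring in seg:
            mask |= polygon_to_mask(ring, shape)
    if not mask.any():
        return None
    return Detection.from_mask(frame_index, mask, score)


def read_detections(path: str | Path) -> dict[int, list[Detection]]:
    """Read per-frame detections from COCO-style JSON or JSON-lines.

    The centroid is always recomputed from the decoded mask pixels, never
    trusted from the file. Zero-area segmentations are skipped with a
    warning.
    """
    path = Path(path)
    text = path.read_text()
    by_frame: dict[int, list[Detection]] = {}

    def _add(det: Detection | None, where: str):
        if det is None:
            warnings.warn(f"skipping empty-mask detection at {where}")
            return
        by_frame.setdefault(det.frame_index, []).append(det)

    stripped = text.lstrip()
    if stripped.startswith("{") and '"annotations"' in text:
        doc = json.loads(text)
        sizes = {img["id"]: (img["height"], img["width"])
                 for img in doc.get("images", [])}
        frame_of = {img["id"]: img.get("frame_index", img["id"])
                    for img in doc.get("images", [])}
        for k, ann in enumerate(doc["annotations"]):
            try:
                img_id = ann["image_id"]
                det = _detection_from_segmentation(
                    int(frame_of.get(img_id, img_id)), ann["segmentation"],
                    sizes.get(img_id), ann.get("score", 1.0))
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"malformed annotation record {k}: {exc}") from exc
            _add(det, f"annotation {k}")
    else:  # JSON-lines
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                seg = rec.get("rle") or rec.get("segmentation")
                shape = tuple(rec["size"]) if "size" in rec else (
                    tuple(seg["size"]) if isinstance(seg, dict) else None)
                det = _detection_from_segmentation(
                    int(rec["frame"]), seg, shape, rec.get("score", 1.0))
            except (KeyError, ValueError, TypeError, json.JSONDecodeError) as exc:
                raise ValueError(f"malformed record on line {lineno}: {exc}") from exc
            _add(det, f"line {lineno}")
    return {k: by_frame[k] for k in sorted(by_frame)}


def write_tracks(path: str | Path,
                 rows: Iterable[tuple[int, int, float, float, float, float, float]],
                 ) -> None:
    """Write per-frame track boxes as a MOTChallenge CSV.

    ``rows`` holds ``(frame, id, x, y, w, h, conf)`` in the package's
    0-based convention; frame numbering in ``rows`` is already 1-based
    (MOT frames start at 1). bb_left/bb_top are converted to MOT's 1-based
    pixels on write. No header, per the MOTChallenge format.
    """
    rows = sorted(rows, key=lambda r: (r[0], r[1]))
    seen = set()
    for r in rows:
        if r[0] < 1 or r[1] < 1:
            raise ValueError(f"frame and id must be >= 1, got {r[:2]}")
        if r[:2] in seen:
            raise ValueError(f"duplicate (frame, id) {r[:2]}")
        seen.add(r[:2])
    with open(path, "w") as fh:
        for frame, tid, x, y, w, h, conf in rows:
            fh.write(f"{frame},{tid},{x + 1:g},{y + 1:g},{w:g},{h:g},"
                     f"{conf:g},-1,-1,-1\n")


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read a MOTChallenge CSV into a DataFrame with 0-based bb_left/bb_top."""
    try:
        df = pd.read_csv(path, header=None, names=MOT_COLUMNS)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=MOT_COLUMNS)
    df["bb_left"] -= 1
    df["bb_top"] -= 1
    return df.sort_values(["frame", "id"], kind="stable").reset_index(drop=True)


def load_frames(path: str | Path) -> FrameSource:
    """Load a directory of PNG/JPEG frames (sorted by filename) or a video
    file readable by imageio."""
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in {".png", ".jpg", ".jpeg"})
        if not files:
            raise FileNotFoundError(f"no image frames in {path}")
        frames = [np.asarray(iio.imread(p))[..., :3] for p in files]
    else:
        if not path.exists():
            raise FileNotFoundError(str(path))
        frames = [np.asarray(f)[..., :3] for f in iio.imiter(path)]
    return FrameSource(frames=frames)
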