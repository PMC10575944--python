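"""Binary-mask utilities: COCO-style RLE codec, polygon rasterization,
gravity centers and bounding boxes.

Masks are boolean ``(H, W)`` arrays. The run-length encoding follows the
COCO "uncompressed RLE" dialect: column-major (Fortran order) run lengths,
always starting with the number of background pixels (possibly 0).
"""

from __future__ import annotations

import numpy as np
from skimage.draw import polygon as _draw_polygon

__all__ = [
    "rle_encode",
    "rle_decode",
    "polygon_to_mask",
    "mask_centroid",
    "mask_bbox",
]


def rle_encode(mask: np.ndarray) -> dict:
    """Encode a boolean mask as uncompressed column-major RLE.

    Returns ``{"counts": [...], "size": [H, W]}``.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    flat = mask.ravel(order="F").astype(np.int8)
    # boundaries between runs
    change = np.flatnonzero(np.diff(flat)) + 1
    edges = np.concatenate(([0], change, [flat.size]))
    counts = np.diff(edges).tolist()
    if flat.size and flat[0] == 1:
        counts = [0] + counts
    if not flat.size:
        counts = [0]
    return {"counts": counts, "size": [int(h), int(w)]}


def rle_decode(rle: dict) -> np.ndarray:
    """Decode uncompressed column-major RLE into a boolean ``(H, W)`` mask."""
    h, w = rle["size"]
    counts = np.asarray(rle["counts"], dtype=np.int64)
    if counts.sum() != h * w:
        raise ValueError(
            f"RLE counts sum to {counts.sum()}, expected {h * w} for size {h}x{w}"
        )
    vals = np.zeros(len(counts), dtype=bool)
    vals[1::2] = True
    flat = np.repeat(vals, counts)
    return flat.reshape((h, w), order="F")


def polygon_to_mask(points, shape) -> np.ndarray:
    """Rasterize a polygon given as a flat ``[x0, y0, x1, y1, ...]`` list or
    an ``(N, 2)`` array of (x, y) vertices into a boolean mask of ``shape``."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(-1, 2)
    rr, cc = _draw_polygon(pts[:, 1], pts[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Gravity center of the foreground: unweighted mean of pixel (x, y)."""
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise ValueError("empty mask has no centroid")
    return float(xs.mean()), float(ys.mean())


def mask_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Tight (x, y, w, h) box of the foreground, half-open extent."""
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise ValueError("empty mask has no bbox")
    x0, x1 = int(xs.min()), int(xs.max())
    y0, y1 = int(ys.min()), int(ys.max())
    return x0, y0, x1 - x0 + 1, y1 - y0 + 1
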