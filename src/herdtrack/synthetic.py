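"""Synthetic overhead scenes for exercising the tracker end to end.

The generator emulates 1 fps top-down footage of a calving pen: a handful
of dark, low-contrast elliptical animals whose coats differ mainly in
procedural *texture* (oriented sinusoidal gratings anchored in object-local
coordinates, so the pattern travels with the animal), smooth random-walk
motion confined to loosely separated regions of the pen, full occlusions
(behind another animal or a static pole), entries and exits, and spurious
short-lived noise detections. Every scene is deterministic given its seed
and ships with exact ground truth and perfect mask detections; a separate
corruption pass degrades the detections for stress tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import CMParams, texture_descriptor, texture_distance
from .io_formats import MOT_COLUMNS, Detection

logger = logging.getLogger(__name__)

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "generate_scene",
    "corrupt_detections",
    "scenario_suite",
]

# dark, low-saturation coat palette (RGB): blacks and browns
PALETTE = [
    (45, 38, 32), (75, 55, 38), (35, 35, 38), (62, 48, 40),
    (50, 42, 48), (80, 62, 45), (40, 45, 42), (68, 52, 52),
]


@dataclass(frozen=True)
class SceneConfig:
    image_size: tuple[int, int] = (512, 512)
    n_objects: int = 5
    n_frames: int = 100
    seed: int = 0
    axes: tuple[float, float] = (30.0, 18.0)  # ellipse semi-axes, px
    step_sigma: float = 6.0                   # random-walk step, px/frame
    momentum: float = 0.7
    texture_amp: float = 28.0
    lookalike: bool = False                   # all objects share one base color
    # events
    occlusions: tuple = ()        # (object_id, start_frame, n_frames)
    pole: tuple | None = None     # (x, y, w, h) static occluder rectangle
    enters: dict = field(default_factory=dict)   # object_id -> frame
    exits: dict = field(default_factory=dict)    # object_id -> frame
    # detection corruption
    miss_rate: float = 0.0
    jitter_sigma: float = 0.0
    merge_probability: float = 0.0
    noise_bursts: tuple = ()      # (start_frame, lifetime, x, y, radius)

    def __post_init__(self):
        for oid, start, length in self.occlusions:
            if not (0 <= start and start + length <= self.n_frames):
                raise ValueError("occlusion outside the sequence")
        for r in (self.miss_rate, self.merge_probability):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")


@dataclass
class GroundTruth:
    """Per-frame, per-object visibility and geometry."""

    records: list = field(default_factory=list)  # dicts

    def add(self, frame, oid, visible, bbox, centroid):
        x, y, w, h = bbox
        self.records.append(dict(frame=frame, id=oid, visible=visible,
                                 x=x, y=y, w=w, h=h,
                                 cx=centroid[0], cy=centroid[1]))

    def to_mot_dataframe(self) -> pd.DataFrame:
        """Visible boxes only, MOT column layout, frames 1-based."""
        rows = [(r["frame"] + 1, r["id"], r["x"], r["y"], r["w"], r["h"],
                 1.0, -1, -1, -1) for r in self.records if r["visible"]]
        return pd.DataFrame(rows, columns=MOT_COLUMNS)

    def trajectory_frames(self, oid) -> list[int]:
        return [r["frame"] for r in self.records
                if r["id"] == oid and r["visible"]]


@dataclass
class _ObjectSpec:
    oid: int
    base: np.ndarray          # (3,) base color
    axes: tuple[float, float]
    pattern: str              # coat-pattern family
    scale: float              # pattern length scale, px
    orient: float             # pattern orientation, radians
    salt: int                 # per-object hash seed for speckle
    tones: tuple              # (rgb_dark, rgb_light) two-tone coat colors
    cell: tuple               # (x0, y0, x1, y1) allowed centre region


def _grid_cells(shape, n, margin):
    h, w = shape
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    cells = []
    for k in range(n):
        r, c = divmod(k, cols)
        x0 = c * w / cols + margin
        x1 = (c + 1) * w / cols - margin
        y0 = r * h / rows + margin
        y1 = (r + 1) * h / rows - margin
        cells.append((x0, y0, x1, y1))
    return cells


def _make_objects(cfg: SceneConfig, rng: np.random.Generator):
    margin = max(cfg.axes) + 4
    cells = _grid_cells(cfg.image_size, cfg.n_objects, margin)
    # structurally different coat-pattern families: their pair statistics
    # differ at every orientation, so the rotation-invariant minimum
    # cannot collapse two animals onto each other
    families = [("speckle", 1.0), ("stripes", 4.5), ("checker", 6.0),
                ("stripes", 14.0), ("spots", 9.0), ("checker", 12.0),
                ("stripes", 8.0), ("spots", 14.0)]
    # coat tones aimed at distinct quantization-bin pairs
    bin_pairs = [(0, 1), (0, 2), (1, 3), (0, 3), (1, 2), (2, 4),
                 (0, 4), (1, 4)]
    objs = []
    for k in range(cfg.n_objects):
        base = np.array(PALETTE[0 if cfg.lookalike else k % len(PALETTE)],
                        dtype=float)
        if not cfg.lookalike:
            base = base + rng.uniform(-4, 4, size=3)
        pattern, scale = families[k % len(families)]
        scale = scale * rng.uniform(0.95, 1.05)
        orient = (0.4 * k + rng.uniform(0, 0.2)) % np.pi
        # look-alikes share base color and tones; only the pattern differs
        b_lo, b_hi = (0, 2) if cfg.lookalike else bin_pairs[k % len(bin_pairs)]
        lum = base.mean()
        tones = tuple(np.clip(base / lum * (32 * b + 20), 0, 255)
                      for b in (b_lo, b_hi))
        axes = (cfg.axes[0] * rng.uniform(0.9, 1.1),
                cfg.axes[1] * rng.uniform(0.9, 1.1))
        objs.append(_ObjectSpec(oid=k + 1, base=base, axes=axes,
                                pattern=pattern, scale=scale, orient=orient,
                                salt=int(rng.integers(1, 2 ** 31)),
                                tones=tones, cell=cells[k]))
    return objs


def _spawn_positions(objs, rng, min_sep, retries=50):
    pos = []
    for o in objs:
        x0, y0, x1, y1 = o.cell
        for _ in range(retries):
            p = np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])
            if all(np.linalg.norm(p - q) >= min_sep for q in pos):
                pos.append(p)
                break
        else:
            raise RuntimeError("could not place objects without overlap")
    return pos


def _object_mask(center, axes, shape):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    u = (xx - center[0]) / axes[0]
    v = (yy - center[1]) / axes[1]
    return u * u + v * v <= 1.0


def _paint(frame, mask, center, spec: _ObjectSpec):
    """Render a two-tone coat; patterns live in object-local coordinates so
    they travel rigidly with the animal."""
    ys, xs = np.nonzero(mask)
    u0 = xs - center[0]
    v0 = ys - center[1]
    c, s = np.cos(spec.orient), np.sin(spec.orient)
    u = u0 * c + v0 * s
    v = -u0 * s + v0 * c
    if spec.pattern == "stripes":
        light = np.sin(2 * np.pi * u / spec.scale) >= 0
    elif spec.pattern == "checker":
        light = (np.sin(2 * np.pi * u / spec.scale)
                 * np.sin(2 * np.pi * v / spec.scale)) >= 0
    elif spec.pattern == "spots":
        g = spec.scale
        light = ((np.mod(u, g) - g / 2) ** 2
                 + (np.mod(v, g) - g / 2) ** 2) <= (0.3 * g) ** 2
    elif spec.pattern == "speckle":
        iu = np.round(u).astype(np.int64)
        iv = np.round(v).astype(np.int64)
        h = (iu * 73856093) ^ (iv * 19349663) ^ spec.salt
        light = (h & 0xFF) < 128
    else:
        raise ValueError(f"unknown pattern {spec.pattern!r}")
    dark, lite = spec.tones
    px = np.where(light[:, None], lite[None, :], dark[None, :])
    frame[ys, xs] = np.clip(px, 0, 255).astype(np.uint8)


def generate_scene(cfg: SceneConfig):
    """Render a scene; returns ``(frames, ground_truth, detections)``.

    ``detections`` are perfect: one per visible object, mask equal to the
    rendered ellipse. At generation time the pairwise texture distance of
    the objects is asserted to exceed their frame-to-frame self-distance,
    so the scene genuinely exercises the texture cue.
    """
    rng = np.random.default_rng(cfg.seed)
    objs = _make_objects(cfg, rng)
    min_sep = 2.4 * max(cfg.axes)
    pos = _spawn_positions(objs, rng, min_sep)
    vel = [np.zeros(2) for _ in objs]

    occluded_at = {}
    for oid, start, length in cfg.occlusions:
        occluded_at.setdefault(oid, []).append((start, start + length))

    def visible(oid, frame):
        if frame < cfg.enters.get(oid, 0):
            return False
        if frame >= cfg.exits.get(oid, cfg.n_frames):
            return False
        return not any(s <= frame < e for s, e in occluded_at.get(oid, []))

    h, w = cfg.image_size
    frames, gt = [], GroundTruth()
    detections: dict[int, list[Detection]] = {}
    bg_noise = rng.integers(-6, 7, size=(h, w, 1))
    background = np.clip(150 + bg_noise, 0, 255).astype(np.uint8)
    background = np.repeat(background, 3, axis=2)

    for f in range(cfg.n_frames):
        frame = background.copy()
        detections[f] = []
        for k, o in enumerate(objs):
            # motion advances even while hidden
            if f > 0:
                vel[k] = cfg.momentum * vel[k] + rng.normal(0, cfg.step_sigma, 2)
                pos[k] = pos[k] + vel[k]
                x0, y0, x1, y1 = o.cell
                for d, (lo, hi) in enumerate(((x0, x1), (y0, y1))):
                    if pos[k][d] < lo:
                        pos[k][d] = lo + (lo - pos[k][d])
                        vel[k][d] = -vel[k][d]
                    elif pos[k][d] > hi:
                        pos[k][d] = hi - (pos[k][d] - hi)
                        vel[k][d] = -vel[k][d]
                    pos[k][d] = float(np.clip(pos[k][d], lo, hi))
            vis = visible(o.oid, f)
            if not vis:
                gt.add(f, o.oid, False, (0, 0, 0, 0), (0.0, 0.0))
                continue
            mask = _object_mask(pos[k], o.axes, (h, w))
            if not mask.any():
                gt.add(f, o.oid, False, (0, 0, 0, 0), (0.0, 0.0))
                continue
            _paint(frame, mask, pos[k], o)
            det = Detection.from_mask(f, mask)
            detections[f].append(det)
            gt.add(f, o.oid, True, det.bbox, det.centroid)
        if cfg.pole is not None:
            px, py, pw, ph = cfg.pole
            frame[py:py + ph, px:px + pw] = (90, 90, 95)
        frames.append(frame)

    _assert_separable(frames, detections, cfg)
    return frames, gt, detections


def _assert_separable(frames, detections, cfg):
    """Objects must be texture-distinguishable, or the scene is useless."""
    f0 = next((f for f in sorted(detections) if len(detections[f]) >= 2), None)
    if f0 is None:
        return
    params = CMParams()
    descs = [texture_descriptor(frames[f0], d.mask, params)
             for d in detections[f0]]
    for i in range(len(descs)):
        for j in range(i + 1, len(descs)):
            d = float(np.nanmean(texture_distance(descs[i], descs[j])))
            if d < 1e-3:
                raise RuntimeError(
                    f"generated textures not separable (pair {i},{j}: {d:g})")


def corrupt_detections(detections: dict[int, list[Detection]],
                       cfg: SceneConfig, seed: int | None = None,
                       ) -> dict[int, list[Detection]]:
    """Degrade perfect detections: misses, centroid jitter, merges of
    overlapping pairs, and short-lived static noise regions."""
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    h, w = cfg.image_size
    out: dict[int, list[Detection]] = {}
    for f in sorted(detections):
        dets = list(detections[f])
        kept = [d for d in dets if rng.random() >= cfg.miss_rate]
        if cfg.jitter_sigma > 0:
            jittered = []
            for d in kept:
                dx, dy = np.round(rng.normal(0, cfg.jitter_sigma, 2)).astype(int)
                mask = np.roll(np.roll(d.mask, dy, axis=0), dx, axis=1)
                jittered.append(Detection.from_mask(f, mask, d.score))
            kept = jittered
        if cfg.merge_probability > 0 and len(kept) >= 2:
            merged, used = [], set()
            for i in range(len(kept)):
                if i in used:
                    continue
                d = kept[i]
                for j in range(i + 1, len(kept)):
                    if j in used:
                        continue
                    if _boxes_touch(d.bbox, kept[j].bbox) and \
                            rng.random() < cfg.merge_probability:
                        d = Detection.from_mask(f, d.mask | kept[j].mask)
                        used.add(j)
                merged.append(d)
            kept = merged
        out[f] = kept
    for start, lifetime, x, y, radius in cfg.noise_bursts:
        mask = _object_mask((x, y), (radius, radius), (h, w))
        for f in range(start, min(start + lifetime, cfg.n_frames)):
            out.setdefault(f, []).append(Detection.from_mask(f, mask, 0.6))
    return out


def _boxes_touch(a, b) -> bool:
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    return ax < bx + bw and bx < ax + aw and ay < by + bh and by < ay + ah


def scenario_suite() -> dict[str, SceneConfig]:
    """Named study scenarios mirroring the situations the tracker must
    survive: clean tracking, re-tracking after full occlusion (gaps of 20
    and 72 frames), entries/exits, noise bursts, and look-alike coats."""
    base = SceneConfig()
    return {
        "clean-5": replace(base, n_objects=5, n_frames=100, seed=11),
        "occlusion-pole-20": replace(
            base, n_objects=3, n_frames=110, seed=21,
            occlusions=((1, 45, 20),), pole=(252, 0, 8, 512)),
        "occlusion-pole-72": replace(
            base, n_objects=3, n_frames=140, seed=22,
            occlusions=((1, 20, 72),), pole=(252, 0, 8, 512)),
        "pairwise-occlusion": replace(
            base, n_objects=4, n_frames=110, seed=31,
            occlusions=((2, 40, 20),)),
        "entry-exit": replace(
            base, n_objects=4, n_frames=120, seed=41,
            enters={4: 30}, exits={2: 80}),
        "noise-burst": replace(
            base, n_objects=5, n_frames=100, seed=51,
            noise_bursts=((20, 5, 256, 256, 9), (45, 8, 100, 420, 8),
                          (70, 5, 420, 80, 10))),
        "lookalike": replace(base, n_objects=2, n_frames=100, seed=61,
                             lookalike=True),
    }
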