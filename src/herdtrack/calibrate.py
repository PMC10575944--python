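"""Calibration of the probation thresholds Th1-Th3 on synthetic scenes.

The raw-distance thresholds that gate the missed-animal decision depend on
detector, resolution and coat statistics, so they are not universal
constants. This module measures, on representative generated scenes, the
distribution of each distance *within* one animal over time (a missing
record against the probation average of the same animal) and *between*
different animals, and places each threshold at the geometric mean of the
within-95th and between-5th percentiles — comfortably above normal
self-variation, comfortably below confusion range.
"""

from __future__ import annotations

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .appearance import StubEmbedder, probability_distance
from .features import (CMParams, ColorMomentVector, TextureDescriptor,
                       color_distance, compute_color_moments,
                       texture_descriptor, texture_distance)
from .synthetic import SceneConfig, generate_scene

__all__ = ["calibrate_thresholds"]


def _avg_color(descs):
    return ColorMomentVector(np.mean([d.values for d in descs], axis=0),
                             descs[0].color_space)


def _avg_texture(descs):
    return TextureDescriptor(np.mean([d.values for d in descs], axis=0),
                             np.logical_and.reduce([d.valid for d in descs]),
                             descs[0].params)


def _tex_scalar(a, b) -> float:
    return float(np.nanmean(texture_distance(a, b)))


def calibrate_thresholds(seed: int = 0, n_frames: int = 60) -> dict:
    """Grid the within/between distance distributions and return
    ``{"th_color", "th_texture", "th_posterior"}``."""
    params = CMParams()
    embedder = StubEmbedder()
    within_c, between_c, within_t, between_t = [], [], [], []
    emb_by_class: dict[tuple, list] = {}

    for scene_seed, lookalike in ((seed + 101, False), (seed + 202, True)):
        cfg = SceneConfig(n_objects=4 if not lookalike else 2,
                          n_frames=n_frames, seed=scene_seed,
                          lookalike=lookalike)
        frames, gt, dets = generate_scene(cfg)
        per_obj: dict[int, dict] = {}
        for f in sorted(dets):
            gts = [r for r in gt.records if r["frame"] == f and r["visible"]]
            for r, det in zip(sorted(gts, key=lambda r: (r["cy"], r["cx"])),
                              sorted(dets[f], key=lambda d: (d.centroid[1],
                                                             d.centroid[0]))):
                x, y, w, h = det.bbox
                crop = frames[f][y:y + h, x:x + w]
                mcrop = det.mask[y:y + h, x:x + w]
                rec = per_obj.setdefault(r["id"], {"c": [], "t": []})
                rec["c"].append(compute_color_moments(crop, mcrop))
                rec["t"].append(texture_descriptor(crop, mcrop, params))
                emb_by_class.setdefault((scene_seed, r["id"]), []).append(
                    embedder(crop, mcrop))
        # within: frame-k snapshot vs average of a later window (the shape
        # of the missed-vs-probation comparison)
        for rec in per_obj.values():
            for k in range(0, n_frames - 30, 10):
                c_avg = _avg_color(rec["c"][k + 5:k + 25])
                t_avg = _avg_texture(rec["t"][k + 5:k + 25])
                within_c.append(color_distance(rec["c"][k], c_avg))
                within_t.append(_tex_scalar(rec["t"][k], t_avg))
        ids = sorted(per_obj)
        for i in ids:
            for j in ids:
                if i == j:
                    continue
                c_avg = _avg_color(per_obj[j]["c"][:25])
                t_avg = _avg_texture(per_obj[j]["t"][:25])
                between_c.append(color_distance(per_obj[i]["c"][0], c_avg))
                between_t.append(_tex_scalar(per_obj[i]["t"][0], t_avg))

    th_color = _split(within_c, between_c)
    th_texture = _split(within_t, between_t)

    # posterior: held-out inverse posterior of the correct class vs others
    keys = sorted(emb_by_class)
    X_tr, y_tr, X_te, y_te = [], [], [], []
    for label, key in enumerate(keys):
        embs = emb_by_class[key]
        half = len(embs) // 2
        X_tr.extend(embs[:half]); y_tr.extend([label] * half)
        X_te.extend(embs[half:]); y_te.extend([label] * (len(embs) - half))
    svm = CalibratedClassifierCV(
        SVC(kernel="rbf", gamma="scale", random_state=seed),
        method="sigmoid", cv=3, ensemble=False)
    svm.fit(np.array(X_tr), np.array(y_tr))
    proba = svm.predict_proba(np.array(X_te))
    correct, wrong = [], []
    for p, label in zip(proba, y_te):
        for k in range(len(keys)):
            (correct if k == label else wrong).append(
                probability_distance(p[k]))
    th_posterior = _split(correct, wrong)
    return {"th_color": _round2(th_color), "th_texture": _round2(th_texture),
            "th_posterior": _round2(th_posterior)}


def _round2(x: float) -> float:
    return float(f"{x:.2g}")


def _split(within, between) -> float:
    """Geometric mean of the within-95th percentile and the between median.

    The between *median* (not minimum) is deliberate: individual pairs may
    legitimately coincide on one cue (look-alike coats have near-zero color
    distance), and the missed-animal decision requires every gate to pass,
    so each single threshold only needs to sit above self-variation and
    below the typical cross-animal distance.
    """
    hi = float(np.percentile(within, 95))
    lo = float(np.median(between))
    if lo <= hi:  # distributions overlap: fall back to just above within
        return 10.0 * max(hi, 1e-12)
    return float(np.sqrt(hi * lo))
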