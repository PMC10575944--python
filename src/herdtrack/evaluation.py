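"""MOT16-style evaluation of a hypothesis track file against ground truth.

Per frame, ground-truth and hypothesis boxes are put in correspondence by
minimum-cost bipartite matching on ``1 - IoU`` (pairs under the IoU
threshold never match), with the MOT16 continuity rule: a ground-truth
object keeps its previous hypothesis when that pairing is still valid.
From the correspondences come FP (unmatched hypotheses), FN (unmatched
ground truth), IDS (a matched ground-truth trajectory changing hypothesis
identity), MOTA = 1 - (FN + FP + IDS)/GT where GT is the total number of
ground-truth boxes, the per-trajectory coverage classes MT (>= 80% of the
life span tracked), ML (<= 20%) and PT (in between), and Frag, the number
of tracked-lost-tracked interruptions of a ground-truth trajectory.
MOTP is intentionally not computed: detector boxes are taken as the true
object locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["MOTMetrics", "iou", "match_frame", "compute_metrics"]


@dataclass(frozen=True)
class MOTMetrics:
    mota: float
    fp: int
    fn: int
    ids: int
    gt: int
    mt: int
    pt: int
    ml: int
    frag: int
    n_trajectories: int

    @property
    def mt_pct(self) -> float:
        return 100.0 * self.mt / self.n_trajectories

    @property
    def ml_pct(self) -> float:
        return 100.0 * self.ml / self.n_trajectories

    def as_dict(self) -> dict:
        return {"MOTA": self.mota, "FP": self.fp, "FN": self.fn,
                "IDS": self.ids, "GT": self.gt, "MT": self.mt, "PT": self.pt,
                "ML": self.ml, "Frag": self.frag,
                "MT_pct": self.mt_pct, "ML_pct": self.ml_pct}


def iou(a, b) -> float:
    """Intersection over union of two (x, y, w, h) boxes."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def match_frame(gt_boxes: dict[int, tuple], hyp_boxes: dict[int, tuple],
                iou_min: float = 0.5,
                prev: dict[int, int] | None = None) -> dict[int, int]:
    """Correspond one frame's boxes: gt id -> hyp id.

    Previous-frame pairings that still satisfy the IoU threshold are kept
    first (continuity rule); the remainder is matched by minimum-cost
    assignment on 1 - IoU.
    """
    prev = prev or {}
    out: dict[int, int] = {}
    free_gt = dict(gt_boxes)
    free_hyp = dict(hyp_boxes)
    for g, h in prev.items():
        if g in free_gt and h in free_hyp and \
                iou(free_gt[g], free_hyp[h]) >= iou_min:
            out[g] = h
            del free_gt[g]
            del free_hyp[h]
    if free_gt and free_hyp:
        g_ids = sorted(free_gt)
        h_ids = sorted(free_hyp)
        cost = np.ones((len(g_ids), len(h_ids)))
        for i, g in enumerate(g_ids):
            for j, h in enumerate(h_ids):
                cost[i, j] = 1.0 - iou(free_gt[g], free_hyp[h])
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if cost[i, j] <= 1.0 - iou_min:
                out[g_ids[i]] = h_ids[j]
    return out


def _boxes_by_frame(df: pd.DataFrame) -> dict[int, dict[int, tuple]]:
    out: dict[int, dict[int, tuple]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(int(row.frame), {})[int(row.id)] = (
            float(row.bb_left), float(row.bb_top),
            float(row.bb_width), float(row.bb_height))
    return out


def compute_metrics(gt: pd.DataFrame, hyp: pd.DataFrame,
                    iou_min: float = 0.5) -> MOTMetrics:
    """Score a hypothesis track table against ground truth.

    Both tables use the MOTChallenge column layout (``frame, id, bb_left,
    bb_top, bb_width, bb_height, ...``); frames are aligned by number.
    """
    if len(gt) == 0:
        raise ValueError("empty ground truth: MOTA undefined")
    gt_frames = _boxes_by_frame(gt)
    hyp_frames = _boxes_by_frame(hyp)
    frames = sorted(set(gt_frames) | set(hyp_frames))

    fp = fn = ids = 0
    total_gt = int(len(gt))
    last_hyp_of: dict[int, int] = {}       # gt id -> last matched hyp id
    matched_frames: dict[int, int] = {}    # gt id -> n frames matched
    prev_corr: dict[int, int] = {}
    tracked_now: dict[int, bool] = {}
    frag: dict[int, int] = {}
    was_tracked: dict[int, bool] = {}      # had a tracked stretch before a gap

    for f in frames:
        g = gt_frames.get(f, {})
        h = hyp_frames.get(f, {})
        corr = match_frame(g, h, iou_min, prev_corr)
        fn += len(g) - len(corr)
        fp += len(h) - len(corr)
        for gid, hid in corr.items():
            if gid in last_hyp_of and last_hyp_of[gid] != hid:
                ids += 1
            last_hyp_of[gid] = hid
            matched_frames[gid] = matched_frames.get(gid, 0) + 1
        for gid in g:
            tracked = gid in corr
            if tracked and was_tracked.get(gid, False) and \
                    not tracked_now.get(gid, True):
                frag[gid] = frag.get(gid, 0) + 1
            if tracked:
                was_tracked[gid] = True
            tracked_now[gid] = tracked
        prev_corr = corr

    traj_ids = sorted(gt["id"].unique())
    span = gt.groupby("id")["frame"].count()
    mt = pt = ml = 0
    for gid in traj_ids:
        rho = matched_frames.get(gid, 0) / int(span[gid])
        if rho >= 0.8:
            mt += 1
        elif rho <= 0.2:
            ml += 1
        else:
            pt += 1
    mota = 1.0 - (fn + fp + ids) / total_gt
    return MOTMetrics(mota=mota, fp=fp, fn=fn, ids=ids, gt=total_gt,
                      mt=mt, pt=pt, ml=ml, frag=int(sum(frag.values())),
                      n_trajectories=len(traj_ids))
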