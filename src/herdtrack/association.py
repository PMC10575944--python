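"""Frame-level data association: gate, featurize, normalize, fuse, assign.

For every surviving track ``p`` and detection ``q`` within the motion gate
(radius ``r``, 350 px by default at the native working resolution), a
feature-distance vector ``F_pq = [L_dist, C_dist, T_dist (12), P_dist]`` is
built. Because these cues live on wildly different scales, each component
is min–max normalized over the frame's gated pairs into [0, 1], the twelve
texture components are collapsed to their mean, and the remaining cues are
fused by a weighted mean into one scalar cost. The frame's matching is the
minimum-total-cost one-to-one assignment restricted to gated pairs
(Hungarian algorithm); a greedy nearest-first matcher is available for
ablation. No motion model is used: detections are associated directly
against last-seen track positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .features import centroid_distance

__all__ = [
    "FeatureDistanceVector",
    "Assignment",
    "gate_candidates",
    "build_feature_vector",
    "normalize_features",
    "combine_cost",
    "assign",
    "DEFAULT_WEIGHTS",
]

# component layout of the stacked feature matrix
N_COMPONENTS = 15  # L, C, T x 12, P
IDX_L, IDX_C = 0, 1
IDX_T = slice(2, 14)
IDX_P = 14

DEFAULT_WEIGHTS = {"location": 0.25, "color": 0.25,
                   "texture": 0.25, "posterior": 0.25}

# raw-appearance sanity bounds for pairs without competition (roughly the
# typical cross-animal color/texture distance on calibration scenes): a
# lone candidate is accepted unless BOTH cues look like a different animal
REJECT_COLOR_RAW = 0.003
REJECT_TEXTURE_RAW = 0.02

_INFEASIBLE = 1e9


@dataclass
class FeatureDistanceVector:
    """Raw distance components for one (track, detection) pair.

    ``texture`` holds 12 components (3 channels x 4 statistics); missing
    entries (thin masks, untrained classifier) are NaN and excluded from
    fusion.
    """

    location: float
    color: float
    texture: np.ndarray
    posterior: float = np.nan

    def as_row(self) -> np.ndarray:
        row = np.empty(N_COMPONENTS)
        row[IDX_L] = self.location
        row[IDX_C] = self.color
        row[IDX_T] = np.asarray(self.texture, dtype=float).ravel()
        row[IDX_P] = self.posterior
        return row


@dataclass
class Assignment:
    matches: list[tuple[int, int]] = field(default_factory=list)
    unmatched_tracks: list[int] = field(default_factory=list)
    unmatched_detections: list[int] = field(default_factory=list)
    match_costs: dict[tuple[int, int], float] = field(default_factory=dict)


def gate_candidates(track_centroids: dict[int, tuple[float, float]],
                    det_centroids: list[tuple[float, float]],
                    r: float = 350.0) -> dict[int, list[int]]:
    """Candidate detections per track: centroid distance <= r (inclusive)."""
    out: dict[int, list[int]] = {}
    for tid, tc in track_centroids.items():
        out[tid] = [qi for qi, dc in enumerate(det_centroids)
                    if centroid_distance(tc, dc) <= r]
    return out


def build_feature_vector(track, det_descriptors, classifier=None,
                         ) -> FeatureDistanceVector:
    """Assemble the raw distance vector for one gated (track, detection) pair.

    ``track`` must carry last-seen ``centroid``, ``color`` and ``texture``
    descriptors; ``det_descriptors`` is the detection's
    ``(centroid, color, texture, embedding)`` tuple. The posterior cue is
    the classifier's posterior for *the track's own class* given the
    detection's embedding, so each candidate pair gets its own P_dist; it
    is NaN (flagged unavailable) before bootstrap or when the track has no
    class yet.
    """
    from .appearance import posterior_for_class, probability_distance
    from .features import color_distance, texture_distance

    centroid, color, texture, embedding = det_descriptors
    if track.color is None or track.texture is None:
        raise ValueError(f"track {track.id} has no stored descriptors")
    t_dist = texture_distance(track.texture, texture).ravel()
    p = np.nan
    if (classifier is not None and embedding is not None
            and classifier.has_class(track.id)):
        post = posterior_for_class(classifier, embedding, track.id)
        p = probability_distance(post)
    return FeatureDistanceVector(
        location=centroid_distance(track.centroid, centroid),
        color=color_distance(track.color, color),
        texture=t_dist,
        posterior=p,
    )


def normalize_features(F: np.ndarray) -> np.ndarray:
    """Min–max normalize each component over the frame's gated pairs.

    A constant column (including the single-pair case) maps to all zeros;
    NaNs (unavailable components) stay NaN.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[0] == 0:
        raise ValueError("need at least one gated pair")
    out = np.full_like(F, np.nan)
    for k in range(F.shape[1]):
        col = F[:, k]
        avail = ~np.isnan(col)
        if not avail.any():
            continue
        lo, hi = col[avail].min(), col[avail].max()
        span = hi - lo
        out[avail, k] = 0.0 if span == 0 else (col[avail] - lo) / span
    return out


def combine_cost(norm_row: np.ndarray,
                 weights: dict[str, float] | None = None) -> float:
    """Fuse one normalized feature row into a scalar cost in [0, 1].

    The 12 texture components are collapsed to their mean first so texture
    does not dominate dimensionally; weights are renormalized over the
    available cues (the posterior cue is absent before the classifier
    bootstraps).
    """
    weights = weights or DEFAULT_WEIGHTS
    row = np.asarray(norm_row, dtype=float)
    tex = row[IDX_T]
    cues = {
        "location": row[IDX_L],
        "color": row[IDX_C],
        "texture": float(np.nanmean(tex)) if not np.all(np.isnan(tex)) else np.nan,
        "posterior": row[IDX_P],
    }
    num = den = 0.0
    for name, value in cues.items():
        w = float(weights.get(name, 0.0))
        if w < 0:
            raise ValueError("weights must be non-negative")
        if np.isnan(value) or w == 0:
            continue
        num += w * value
        den += w
    if den == 0:
        raise ValueError("no available feature components to fuse")
    return num / den


def assign(cost: np.ndarray, track_ids: list[int], n_detections: int,
           gated: np.ndarray, l_dist: np.ndarray | None = None,
           max_cost: float | None = None, matcher: str = "hungarian",
           ) -> Assignment:
    """Solve the frame's one-to-one matching on a (tracks x detections)
    cost matrix restricted to gated pairs.

    Ties are broken toward the smaller location distance, then the lower
    track index, via an infinitesimal cost perturbation. Matches with fused
    cost above ``max_cost`` are rejected to unmatched rather than forced.
    """
    cost = np.asarray(cost, dtype=float)
    gated = np.asarray(gated, dtype=bool)
    n_t, n_d = cost.shape
    if n_d != n_detections or n_t != len(track_ids):
        raise ValueError("cost matrix shape mismatch")
    work = np.where(gated, cost, _INFEASIBLE)
    if l_dist is not None and work.size:
        # deterministic tie-breaks; small enough not to change the optimum
        work = work + 1e-9 * np.asarray(l_dist) / max(1.0, np.nanmax(l_dist) or 1.0)
    work = work + 1e-12 * np.arange(n_t)[:, None]

    matches: list[tuple[int, int]] = []
    if matcher == "hungarian":
        if n_t and n_d:
            rows, cols = linear_sum_assignment(work)
            matches = [(int(r), int(c)) for r, c in zip(rows, cols)]
    elif matcher == "greedy":
        order = np.argsort(work, axis=None, kind="stable")
        used_r: set[int] = set()
        used_c: set[int] = set()
        for flat in order:
            r, c = divmod(int(flat), n_d)
            if r in used_r or c in used_c:
                continue
            used_r.add(r)
            used_c.add(c)
            matches.append((r, c))
    else:
        raise ValueError(f"unknown matcher {matcher!r}")

    result = Assignment()
    matched_r: set[int] = set()
    matched_c: set[int] = set()
    for r, c in matches:
        if not gated[r, c]:
            continue
        if max_cost is not None and cost[r, c] > max_cost:
            continue
        result.matches.append((track_ids[r], c))
        result.match_costs[(track_ids[r], c)] = float(cost[r, c])
        matched_r.add(r)
        matched_c.add(c)
    result.unmatched_tracks = [track_ids[r] for r in range(n_t)
                               if r not in matched_r]
    result.unmatched_detections = [c for c in range(n_d) if c not in matched_c]
    return result
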