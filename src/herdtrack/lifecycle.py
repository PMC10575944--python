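"""Track lifecycle: identity bookkeeping, the missing-object database, and
the probation of newly detected objects.

A detection the frame matcher cannot explain receives a *temporary* track
that is observed for ``age_temp`` frames (30 by default, i.e. 30 s at
1 fps) before being classified:

* **noise** — seen for fewer than half of the first ``age_temp/2`` frames:
  deleted, together with any buffered crops, so a spurious detector blob
  never becomes a permanent identity (this is what drives FP toward zero);
* **missed animal** — its averaged appearance lies within the color,
  texture and posterior thresholds of some record in the missing-object
  database, and its birth location is plausibly reachable from where that
  animal vanished: the old identity resumes;
* **new animal** — otherwise: the next unused permanent id is assigned.

Thresholds compare *raw* (unnormalized) distances, so they are calibrated
once on representative scenes rather than per frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .features import (ColorMomentVector, TextureDescriptor, centroid_distance,
                       color_distance, texture_distance)

logger = logging.getLogger(__name__)

__all__ = [
    "Track",
    "MissingRecord",
    "TempTrack",
    "Thresholds",
    "init_tracks",
    "mark_missing",
    "spawn_temp",
    "update_temp",
    "average_appearance",
    "noise_check",
    "classify_temp",
]


@dataclass
class Track:
    """A persistent identity with its last-seen geometry and descriptors."""

    id: int
    state: str = "active"  # active | missing
    centroid: tuple[float, float] = (0.0, 0.0)
    bbox: tuple[int, int, int, int] = (0, 0, 0, 0)
    color: ColorMomentVector | None = None
    texture: TextureDescriptor | None = None
    last_seen: int = 0
    score: float = 1.0


@dataclass
class MissingRecord:
    """Frozen last-seen information for a track that left view."""

    track_id: int
    centroid: tuple[float, float]
    color: ColorMomentVector
    texture: TextureDescriptor
    frame_entered: int


@dataclass
class TempTrack:
    """A provisional identity under probation."""

    temp_id: int
    born_frame: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int] = (0, 0, 0, 0)
    n_seen: int = 1  # N_c: frames observed since birth, inclusive
    color: ColorMomentVector | None = None
    texture: TextureDescriptor | None = None
    first_centroid: tuple[float, float] = (0.0, 0.0)
    color_history: list[ColorMomentVector] = field(default_factory=list)
    texture_history: list[TextureDescriptor] = field(default_factory=list)
    embedding_history: list[np.ndarray] = field(default_factory=list)
    noise_checked: bool = False


@dataclass(frozen=True)
class Thresholds:
    """Raw-distance gates of the missed-animal test.

    ``color`` bounds the cosine distance of averaged color moments,
    ``texture`` the mean of the averaged rotation-invariant texture
    components, ``posterior`` the averaged inverse posterior 1/P. Defaults come from
    the shipped calibration procedure on the synthetic scene suite.
    """

    color: float = 4.5e-5
    texture: float = 0.011
    posterior: float = 17.0

    def __post_init__(self):
        if min(self.color, self.texture, self.posterior) <= 0:
            raise ValueError("thresholds must be positive")


def init_tracks(detections, frame_index: int = 0) -> list[Track]:
    """Assign ids 1..M to the first frame's detections in reading order
    (sorted by centroid y, then x)."""
    order = sorted(range(len(detections)),
                   key=lambda i: (detections[i].centroid[1],
                                  detections[i].centroid[0]))
    tracks = []
    for tid, i in enumerate(order, start=1):
        d = detections[i]
        tracks.append(Track(id=tid, centroid=d.centroid, bbox=d.bbox,
                            last_seen=frame_index, score=d.score))
    return tracks


def mark_missing(track: Track, frame_index: int,
                 db: dict[int, MissingRecord]) -> MissingRecord:
    """Move an unmatched active track into the missing-object database.

    Idempotent: a second call returns the existing record unchanged.
    """
    if track.id in db:
        return db[track.id]
    track.state = "missing"
    rec = MissingRecord(track_id=track.id, centroid=track.centroid,
                        color=track.color, texture=track.texture,
                        frame_entered=frame_index)
    db[track.id] = rec
    logger.debug("track %d missing at frame %d", track.id, frame_index)
    return rec


def spawn_temp(detection, frame_index: int, temp_id: int,
               descriptors=None, embedding=None) -> TempTrack:
    """Open probation for an unexplained detection."""
    t = TempTrack(temp_id=temp_id, born_frame=frame_index,
                  centroid=detection.centroid, bbox=detection.bbox,
                  first_centroid=detection.centroid)
    if descriptors is not None:
        color, texture = descriptors
        t.color, t.texture = color, texture
        t.color_history.append(color)
        t.texture_history.append(texture)
    if embedding is not None:
        t.embedding_history.append(np.asarray(embedding, dtype=float))
    return t


def update_temp(temp: TempTrack, matched: bool, detection=None,
                descriptors=None, embedding=None) -> TempTrack:
    """Advance a temp track one frame; N_c counts cumulative sightings."""
    if not matched:
        return temp
    temp.n_seen += 1
    if detection is not None:
        temp.centroid = detection.centroid
        temp.bbox = detection.bbox
    if descriptors is not None:
        color, texture = descriptors
        temp.color, temp.texture = color, texture
        temp.color_history.append(color)
        temp.texture_history.append(texture)
    if embedding is not None:
        temp.embedding_history.append(np.asarray(embedding, dtype=float))
    return temp


def average_appearance(temp: TempTrack
                       ) -> tuple[ColorMomentVector, TextureDescriptor]:
    """Component-wise mean of the probation history's descriptors."""
    if not temp.color_history:
        raise ValueError("temp track has no descriptor history")
    cvals = np.mean([c.values for c in temp.color_history], axis=0)
    c_avg = ColorMomentVector(values=cvals,
                              color_space=temp.color_history[0].color_space)
    tvals = np.mean([t.values for t in temp.texture_history], axis=0)
    valid = np.logical_and.reduce([t.valid for t in temp.texture_history])
    t_avg = TextureDescriptor(values=tvals, valid=valid,
                              params=temp.texture_history[0].params)
    return c_avg, t_avg


def noise_check(temp: TempTrack, frame_index: int, age_temp: int = 30) -> bool:
    """Mid-probation check: True means the temp is noise and must die.

    Fires once at ``born + age_temp/2``; an object seen for fewer than
    half of those frames (cumulative) is classified as noise.
    """
    mid = temp.born_frame + age_temp // 2
    if frame_index < mid or temp.noise_checked:
        return False
    temp.noise_checked = True
    return temp.n_seen < age_temp // 2


def classify_temp(temp: TempTrack, missing_db: dict[int, MissingRecord],
                  classifier, thresholds: Thresholds, next_new_id: int,
                  r_missing: float = 700.0) -> tuple[str, int]:
    """Final probation decision at ``born + age_temp``.

    Returns ``("missed", resumed_id)`` when some missing record satisfies
    all raw-distance gates, else ``("new", next_new_id)``. When several
    records qualify the one with the lowest mean of the three gate ratios
    wins. The posterior gate is skipped when no classifier is trained or
    the record's class is not in the model (the animal may have vanished
    before bootstrap).
    """
    from .appearance import posterior_for_class, probability_distance

    c_avg, t_avg = average_appearance(temp)
    best: tuple[float, int] | None = None
    for rec in missing_db.values():
        l_dist = centroid_distance(rec.centroid, temp.first_centroid)
        if l_dist > r_missing:
            continue
        c_dist = color_distance(rec.color, c_avg)
        if c_dist >= thresholds.color:
            continue
        t_comp = texture_distance(rec.texture, t_avg)
        t_scalar = float(np.nanmean(t_comp)) if not np.all(np.isnan(t_comp)) \
            else np.inf
        if t_scalar >= thresholds.texture:
            continue
        score_terms = [c_dist / thresholds.color, t_scalar / thresholds.texture]
        if (classifier is not None and classifier.has_class(rec.track_id)
                and temp.embedding_history):
            posts = [posterior_for_class(classifier, e, rec.track_id)
                     for e in temp.embedding_history]
            p_dist_avg = float(np.mean([probability_distance(p) for p in posts]))
            if p_dist_avg >= thresholds.posterior:
                continue
            score_terms.append(p_dist_avg / thresholds.posterior)
        score = float(np.mean(score_terms))
        if best is None or score < best[0] or (
                score == best[0] and rec.track_id < best[1]):
            best = (score, rec.track_id)
    if best is not None:
        logger.info("temp %d resumes missing id %d", temp.temp_id, best[1])
        return "missed", best[1]
    logger.info("temp %d becomes new id %d", temp.temp_id, next_new_id)
    return "new", next_new_id
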