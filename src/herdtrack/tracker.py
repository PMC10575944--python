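"""The per-frame tracking loop.

Each frame is processed in a fixed order: (1) gate and associate active
tracks against the frame's detections using the fused
location/color/texture/posterior cost; (2) update matched tracks and admit
their crops to the appearance buffer; (3) move unmatched tracks to the
missing-object database; (4) offer unmatched detections to the temporary
tracks under probation, spawning new temps for whatever remains;
(5) resolve probations on schedule (noise / missed / new); (6) retrain the
appearance classifier on its interval; (7) emit the frame's active track
boxes. Identities are created on the first frame in reading order and
afterwards only through the probation machinery.

Before the classifier bootstraps (30 crops per animal), association runs
on the three hand-crafted cues alone — the cold-start mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import association as assoc
from . import lifecycle as lc
from .appearance import AppearanceBuffer, ClassifierModel, get_embedder, \
    maybe_retrain
from .config import TrackerConfig
from .features import CMParams, compute_color_moments, texture_descriptor
from .io_formats import Detection

logger = logging.getLogger(__name__)

__all__ = ["TrackerState", "Tracker", "run"]


@dataclass
class TrackerState:
    tracks: dict[int, lc.Track] = field(default_factory=dict)
    missing_db: dict[int, lc.MissingRecord] = field(default_factory=dict)
    temps: dict[int, lc.TempTrack] = field(default_factory=dict)
    classifier: ClassifierModel | None = None
    buffer: AppearanceBuffer = field(default_factory=AppearanceBuffer)
    frame_clock: int = -1
    next_track_id: int = 1
    next_temp_id: int = 1
    initialized: bool = False

    def active_tracks(self) -> list[lc.Track]:
        return [t for t in self.tracks.values() if t.state == "active"]


class Tracker:
    """Stateful frame-by-frame tracker; see module docstring for the loop."""

    def __init__(self, config: TrackerConfig | None = None):
        self.config = config or TrackerConfig()
        self.state = TrackerState(
            buffer=AppearanceBuffer(capacity=self.config.buffer_capacity))
        self.embedder = get_embedder(self.config.embedder)
        self.cm_params = CMParams(levels=self.config.cm_levels,
                                  distance=self.config.cm_distance,
                                  symmetric=self.config.cm_symmetric,
                                  color_space=self.config.color_space_texture)
        self.events: list[dict] = []

    # -- descriptor plumbing -------------------------------------------------

    def _describe(self, frame: np.ndarray, det: Detection):
        """(centroid, color, texture, embedding) of one detection."""
        x, y, w, h = det.bbox
        crop = frame[y:y + h, x:x + w]
        mcrop = det.mask[y:y + h, x:x + w]
        color = compute_color_moments(crop, mcrop,
                                      self.config.color_space_moments)
        texture = texture_descriptor(crop, mcrop, self.cm_params)
        embedding = self.embedder(crop, mcrop)
        return det.centroid, color, texture, embedding

    def _log(self, frame: int, kind: str, **info):
        self.events.append({"frame": frame, "event": kind, **info})

    # -- association helpers -------------------------------------------------

    def _associate(self, entries, det_desc, det_indices, classifier):
        """Gate + featurize + normalize + fuse + assign.

        ``entries`` is a list of track-like objects with id/centroid/
        color/texture. Returns an Assignment over (entry id, detection
        index into det_indices).
        """
        cfg = self.config
        n_t, n_d = len(entries), len(det_indices)
        gated = np.zeros((n_t, n_d), dtype=bool)
        l_dist = np.full((n_t, n_d), np.nan)
        raw_rows, pair_pos = [], []
        for r, tr in enumerate(entries):
            for c, qi in enumerate(det_indices):
                d = assoc.centroid_distance(tr.centroid, det_desc[qi][0])
                if d <= cfg.r_px:
                    gated[r, c] = True
                    l_dist[r, c] = d
                    fv = assoc.build_feature_vector(tr, det_desc[qi], classifier)
                    raw_rows.append(fv.as_row())
                    pair_pos.append((r, c))
        cost = np.full((n_t, n_d), np.inf)
        if raw_rows:
            raw = np.vstack(raw_rows)
            norm = assoc.normalize_features(raw)
            for row, (r, c) in zip(norm, pair_pos):
                cost[r, c] = assoc.combine_cost(row, cfg.weights)
            # a pair without competition has no meaningful per-frame scale:
            # exempt it from max_cost, but drop it when both raw appearance
            # cues look like a different animal
            row_n = gated.sum(axis=1)
            col_n = gated.sum(axis=0)
            for raw_row, (r, c) in zip(raw, pair_pos):
                if row_n[r] == 1 and col_n[c] == 1:
                    c_raw = raw_row[assoc.IDX_C]
                    t_raw = float(np.nanmean(raw_row[assoc.IDX_T]))
                    if (c_raw > assoc.REJECT_COLOR_RAW
                            and t_raw > assoc.REJECT_TEXTURE_RAW):
                        gated[r, c] = False
                        cost[r, c] = np.inf
                    else:
                        cost[r, c] = 0.0
        return assoc.assign(cost, [tr.id for tr in entries], n_d, gated,
                            l_dist=np.nan_to_num(l_dist, nan=0.0),
                            max_cost=cfg.max_cost, matcher=cfg.matcher)

    # -- the loop ------------------------------------------------------------

    def step(self, frame: np.ndarray, detections: list[Detection],
             frame_index: int) -> list[tuple[int, int, float, float, float, float, float]]:
        """Process one frame; returns emitted (frame, id, x, y, w, h, conf)
        rows in MOT numbering (frame and ids 1-based)."""
        st, cfg = self.state, self.config
        if frame_index <= st.frame_clock:
            raise ValueError(f"frame index regression: {frame_index} after "
                             f"{st.frame_clock}")
        st.frame_clock = frame_index

        det_desc = [self._describe(frame, d) for d in detections]
        emitted: list[int] = []

        if not st.initialized:
            st.initialized = True
            order = sorted(range(len(detections)),
                           key=lambda i: (detections[i].centroid[1],
                                          detections[i].centroid[0]))
            for tr, i in zip(lc.init_tracks(detections, frame_index), order):
                _, tr.color, tr.texture, emb = det_desc[i]
                st.tracks[tr.id] = tr
                st.buffer.add(tr.id, frame_index, emb)
                emitted.append(tr.id)
            st.next_track_id = len(st.tracks) + 1
            self._log(frame_index, "init", n_tracks=len(st.tracks))
            return self._emit(frame_index, emitted)

        # (1) active tracks vs detections
        active = sorted(st.active_tracks(), key=lambda t: t.id)
        result = self._associate(active, det_desc, list(range(len(detections))),
                                 st.classifier)

        # (2) matched updates
        for tid, qi in result.matches:
            tr = st.tracks[tid]
            det = detections[qi]
            _, color, texture, emb = det_desc[qi]
            tr.centroid, tr.bbox = det.centroid, det.bbox
            tr.color, tr.texture = color, texture
            tr.last_seen, tr.score = frame_index, det.score
            if result.match_costs[(tid, qi)] <= cfg.buffer_admit_max_cost:
                st.buffer.add(tid, frame_index, emb)
            emitted.append(tid)

        # (3) unmatched tracks -> missing
        for tid in result.unmatched_tracks:
            lc.mark_missing(st.tracks[tid], frame_index, st.missing_db)
            self._log(frame_index, "missing", track=tid)

        # (4) leftover detections -> temps (second association pass)
        leftover = list(result.unmatched_detections)
        temp_matched: dict[int, int] = {}
        temps = sorted(st.temps.values(), key=lambda t: t.temp_id)
        temps_with_desc = [t for t in temps if t.color is not None]
        if temps_with_desc and leftover:
            tres = self._associate(
                [_TempView(t) for t in temps_with_desc], det_desc, leftover,
                None)
            for temp_id, ci in tres.matches:
                temp_matched[temp_id] = leftover[ci]
            leftover = [leftover[ci] for ci in tres.unmatched_detections]
        for temp_id, temp in ((t.temp_id, t) for t in temps):
            if temp_id in temp_matched:
                qi = temp_matched[temp_id]
                _, color, texture, emb = det_desc[qi]
                lc.update_temp(temp, True, detections[qi], (color, texture), emb)
            else:
                lc.update_temp(temp, False)
        for qi in leftover:
            _, color, texture, emb = det_desc[qi]
            temp = lc.spawn_temp(detections[qi], frame_index, st.next_temp_id,
                                 (color, texture), emb)
            st.temps[st.next_temp_id] = temp
            self._log(frame_index, "spawn_temp", temp=st.next_temp_id)
            st.next_temp_id += 1

        # (5) probation decisions
        for temp in list(st.temps.values()):
            if lc.noise_check(temp, frame_index, cfg.age_temp_frames):
                del st.temps[temp.temp_id]
                self._log(frame_index, "noise", temp=temp.temp_id,
                          n_seen=temp.n_seen)
                continue
            if frame_index < temp.born_frame + cfg.age_temp_frames:
                continue
            decision, tid = lc.classify_temp(
                temp, st.missing_db, st.classifier, cfg.thresholds(),
                st.next_track_id, cfg.r_missing)
            del st.temps[temp.temp_id]
            if decision == "missed":
                tr = st.tracks[tid]
                tr.state = "active"
                del st.missing_db[tid]
            else:
                tr = lc.Track(id=tid)
                st.tracks[tid] = tr
                st.next_track_id = tid + 1
            tr.centroid, tr.bbox = temp.centroid, temp.bbox
            tr.color, tr.texture = temp.color, temp.texture
            tr.last_seen = frame_index
            for emb in temp.embedding_history:
                st.buffer.add(tid, frame_index, emb)
            self._log(frame_index, decision, temp=temp.temp_id, track=tid)
            if temp.temp_id in temp_matched:  # visible right now
                emitted.append(tid)

        # expire stale missing records
        for tid, rec in list(st.missing_db.items()):
            if frame_index - rec.frame_entered > cfg.max_missing_frames:
                del st.missing_db[tid]
                st.tracks.pop(tid, None)
                self._log(frame_index, "expire_missing", track=tid)

        # (6) classifier maintenance
        before = st.classifier
        st.classifier = maybe_retrain(
            st.classifier, st.buffer, [t.id for t in st.active_tracks()],
            frame_index, cfg.retrain_interval_frames, cfg.min_per_class,
            cfg.seed)
        if st.classifier is not before:
            self._log(frame_index, "retrain",
                      classes=list(st.classifier.classes))

        # (7) emit
        return self._emit(frame_index, emitted)

    def _emit(self, frame_index: int, track_ids: list[int]):
        rows = []
        for tid in sorted(set(track_ids)):
            tr = self.state.tracks[tid]
            x, y, w, h = tr.bbox
            rows.append((frame_index + 1, tid, float(x), float(y),
                         float(w), float(h), float(tr.score)))
        return rows


class _TempView:
    """Adapter giving a TempTrack the track interface _associate expects."""

    def __init__(self, temp: lc.TempTrack):
        self.id = temp.temp_id
        self.centroid = temp.centroid
        self.color = temp.color
        self.texture = temp.texture


def run(frames, detections_by_frame: dict[int, list[Detection]],
        config: TrackerConfig | None = None):
    """Track a whole sequence.

    ``frames`` is an indexable sequence of RGB frames; detections are a
    mapping frame_index -> detections. Returns ``(rows, log)`` where rows
    are MOT-numbered track boxes and log is a structured run record.
    Deterministic for a fixed config and seed.
    """
    config = config or TrackerConfig()
    tracker = Tracker(config)
    rows: list[tuple] = []
    for fi in range(len(frames)):
        rows.extend(tracker.step(frames[fi], detections_by_frame.get(fi, []), fi))
    log = {"config": config.to_dict(), "n_frames": len(frames),
           "events": tracker.events}
    return rows, log
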