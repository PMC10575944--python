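import numpy as np
import pytest

from herdtrack.features import (CMParams, ColorMomentVector,
                                TextureDescriptor)
from herdtrack.io_formats import Detection
from herdtrack.lifecycle import (Thresholds, Track, average_appearance,
                                 classify_temp, init_tracks, mark_missing,
                                 noise_check, spawn_temp, update_temp,
                                 MissingRecord)


def _det(cx, cy, frame=0):
    mask = np.zeros((200, 200), dtype=bool)
    mask[int(cy) - 2:int(cy) + 3, int(cx) - 2:int(cx) + 3] = True
    return Detection.from_mask(frame, mask)


def _color(values):
    return ColorMomentVector(np.asarray(values, dtype=float).reshape(3, 3))


def _texture(scale):
    vals = np.full((3, 4, 4), float(scale))
    return TextureDescriptor(vals, np.ones((3, 4), dtype=bool), CMParams())


class TestInit:
    def test_reading_order_ids(self):
        dets = [_det(50, 100), _det(20, 20), _det(80, 20)]
        tracks = init_tracks(dets)
        assert [t.id for t in tracks] == [1, 2, 3]
        # sorted by y then x: (20,20) first, (80,20), then (50,100)
        assert tracks[0].centroid == dets[1].centroid
        assert tracks[1].centroid == dets[2].centroid
        assert tracks[2].centroid == dets[0].centroid

    def test_empty_frame(self):
        assert init_tracks([]) == []

    def test_deterministic(self):
        dets = [_det(50, 100), _det(20, 20)]
        a = [(t.id, t.centroid) for t in init_tracks(dets)]
        b = [(t.id, t.centroid) for t in init_tracks(dets)]
        assert a == b


class TestMissing:
    def _track(self):
        return Track(id=3, centroid=(10.0, 20.0), color=_color(range(9)),
                     texture=_texture(1.0), last_seen=5)

    def test_record_freezes_last_seen_state(self):
        db = {}
        tr = self._track()
        rec = mark_missing(tr, 7, db)
        assert tr.state == "missing"
        assert rec.centroid == (10.0, 20.0)
        assert rec.frame_entered == 7
        assert rec.color is tr.color

    def test_idempotent(self):
        db = {}
        tr = self._track()
        r1 = mark_missing(tr, 7, db)
        r2 = mark_missing(tr, 9, db)
        assert r1 is r2 and len(db) == 1
        assert r1.frame_entered == 7


class TestTempTracks:
    def test_spawn_counts_birth(self):
        t = spawn_temp(_det(30, 30), frame_index=10, temp_id=1)
        assert t.n_seen == 1 and t.born_frame == 10

    def test_distinct_temp_ids(self):
        a = spawn_temp(_det(30, 30), 0, temp_id=1)
        b = spawn_temp(_det(90, 90), 0, temp_id=2)
        assert a.temp_id != b.temp_id

    def test_matched_updates_count_and_history(self):
        t = spawn_temp(_det(30, 30), 0, 1,
                       descriptors=(_color(range(9)), _texture(1)))
        for i in range(15):
            update_temp(t, True, _det(31 + i, 30),
                        descriptors=(_color(range(9)), _texture(1)))
        assert t.n_seen == 16
        assert len(t.color_history) == t.n_seen

    def test_unmatched_frame_leaves_count(self):
        t = spawn_temp(_det(30, 30), 0, 1)
        update_temp(t, False)
        assert t.n_seen == 1


class TestNoiseCheck:
    def test_sparse_temp_is_noise_at_midpoint(self):
        t = spawn_temp(_det(30, 30), 0, 1)
        t.n_seen = 10
        assert not noise_check(t, 14, age_temp=30)
        assert noise_check(t, 15, age_temp=30)

    def test_busy_temp_survives(self):
        t = spawn_temp(_det(30, 30), 0, 1)
        t.n_seen = 15
        assert not noise_check(t, 15, age_temp=30)

    def test_check_fires_once(self):
        t = spawn_temp(_det(30, 30), 0, 1)
        t.n_seen = 15
        noise_check(t, 15, age_temp=30)
        t.n_seen = 15  # still sparse later on, but already checked
        assert not noise_check(t, 20, age_temp=30)


class TestAverageAppearance:
    def test_single_entry_is_itself(self):
        c = _color(range(9))
        t = spawn_temp(_det(30, 30), 0, 1, descriptors=(c, _texture(2)))
        c_avg, t_avg = average_appearance(t)
        assert np.array_equal(c_avg.values, c.values)
        assert np.allclose(t_avg.values, 2)

    def test_mean_matches_direct_computation(self, rng):
        t = spawn_temp(_det(30, 30), 0, 1,
                       descriptors=(_color(rng.uniform(0, 9, 9)),
                                    _texture(rng.uniform())))
        vals = [t.color_history[0].values]
        for _ in range(5):
            c = _color(rng.uniform(0, 9, 9))
            vals.append(c.values)
            update_temp(t, True, descriptors=(c, _texture(rng.uniform())))
        c_avg, _ = average_appearance(t)
        assert np.allclose(c_avg.values, np.mean(vals, axis=0))


class TestClassifyTemp:
    def _temp(self, color, texture, centroid=(30, 30)):
        t = spawn_temp(_det(*centroid), 0, 1,
                       descriptors=(color, texture))
        t.n_seen = 30
        return t

    def _record(self, tid, color, texture, centroid=(40, 40)):
        return MissingRecord(track_id=tid, centroid=centroid, color=color,
                             texture=texture, frame_entered=0)

    def test_matching_record_resumes_id(self):
        c, tx = _color([5, 1, 0, 4, 1, 0, 3, 1, 0]), _texture(1.0)
        db = {7: self._record(7, c, tx)}
        decision, tid = classify_temp(self._temp(c, tx), db, None,
                                      Thresholds(), next_new_id=9)
        assert (decision, tid) == ("missed", 7)

    def test_appearance_mismatch_creates_new_id(self):
        db = {7: self._record(7, _color([9, 0, 0, 0, 9, 0, 0, 0, 9]),
                              _texture(5.0))}
        temp = self._temp(_color([0, 0, 9, 9, 0, 0, 0, 9, 0]), _texture(1.0))
        decision, tid = classify_temp(temp, db, None, Thresholds(), 9)
        assert (decision, tid) == ("new", 9)

    def test_distant_record_not_resumed(self):
        c, tx = _color([5, 1, 0, 4, 1, 0, 3, 1, 0]), _texture(1.0)
        db = {7: self._record(7, c, tx, centroid=(1800, 1800))}
        decision, tid = classify_temp(self._temp(c, tx), db, None,
                                      Thresholds(), 9, r_missing=700)
        assert (decision, tid) == ("new", 9)

    def test_empty_db_creates_new_id(self):
        temp = self._temp(_color(range(9)), _texture(1.0))
        assert classify_temp(temp, {}, None, Thresholds(), 4) == ("new", 4)

    def test_best_of_several_matching_records_wins(self):
        c, tx = _color([5, 1, 0, 4, 1, 0, 3, 1, 0]), _texture(1.0)
        near_vals = c.values.copy()
        near_vals[0, 0] *= 1.001  # slightly off in direction, within gate
        db = {2: self._record(2, _color(near_vals.ravel()), tx),
              5: self._record(5, c, tx)}
        decision, tid = classify_temp(self._temp(c, tx), db, None,
                                      Thresholds(), 9)
        assert (decision, tid) == ("missed", 5)
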