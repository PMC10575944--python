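import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from herdtrack.features import (ANGLES, CMParams, NoPairsError,
                                TextureDescriptor, centroid_distance,
                                cm_features, color_distance, compute_cm,
                                compute_color_moments, quantize_channel,
                                texture_descriptor, texture_distance)

# offsets must agree with the implementation's angle convention
OFFSETS = {0: (1, 0), 45: (1, -1), 90: (0, -1), 135: (-1, -1)}


def brute_force_cm(q, mask, levels, angle, distance=1, symmetric=True):
    """Independent pair-counting oracle: explicit double loop."""
    h, w = q.shape
    dx, dy = OFFSETS[angle]
    dx, dy = dx * distance, dy * distance
    counts = np.zeros((levels, levels))
    for y in range(h):
        for x in range(w):
            x2, y2 = x + dx, y + dy
            if 0 <= x2 < w and 0 <= y2 < h and mask[y, x] and mask[y2, x2]:
                counts[q[y, x], q[y2, x2]] += 1
                if symmetric:
                    counts[q[y2, x2], q[y, x]] += 1
    if counts.sum() == 0:
        return None
    return counts / counts.sum()


class TestColorMoments:
    def test_constant_region(self):
        frame = np.full((5, 5, 3), 100, dtype=np.uint8)
        mask = np.ones((5, 5), dtype=bool)
        cm = compute_color_moments(frame, mask, "rgb")
        assert np.allclose(cm.values[:, 0], 100)  # mean
        assert np.allclose(cm.values[:, 1], 0)    # sigma
        assert np.allclose(cm.values[:, 2], 0)    # skewness defined as 0

    def test_symmetric_two_pixel_region(self):
        frame = np.zeros((1, 2, 3), dtype=np.uint8)
        frame[0, 1] = 2
        mask = np.ones((1, 2), dtype=bool)
        cm = compute_color_moments(frame, mask, "rgb")
        assert np.allclose(cm.values[:, 0], 1)
        assert np.allclose(cm.values[:, 1], 1)
        assert np.allclose(cm.values[:, 2], 0)

    def test_matches_direct_summation(self, rng):
        frame = rng.integers(0, 256, size=(5, 5, 3), dtype=np.uint8)
        mask = rng.random((5, 5)) < 0.7
        mask[0, 0] = True
        cm = compute_color_moments(frame, mask, "rgb")
        px = frame[mask].astype(float)
        for c in range(3):
            mu = px[:, c].sum() / len(px)
            sig = np.sqrt(((px[:, c] - mu) ** 2).sum() / len(px))
            m3 = ((px[:, c] - mu) ** 3).sum() / len(px)
            skew = m3 / sig ** 3 if sig > 0 else 0.0
            assert cm.values[c] == pytest.approx([mu, sig, skew])

    def test_only_mask_pixels_contribute(self):
        frame = np.zeros((4, 4, 3), dtype=np.uint8)
        frame[0, 0] = 200
        mask = np.zeros((4, 4), dtype=bool)
        mask[2:, 2:] = True
        cm = compute_color_moments(frame, mask, "rgb")
        assert np.allclose(cm.values[:, 0], 0)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            compute_color_moments(np.zeros((3, 3, 3), dtype=np.uint8),
                                  np.zeros((3, 3), dtype=bool))


class TestColorDistance:
    def _vec(self, values):
        from herdtrack.features import ColorMomentVector
        return ColorMomentVector(np.asarray(values, dtype=float).reshape(3, 3))

    def test_identity_is_zero(self):
        a = self._vec(np.arange(1, 10))
        assert color_distance(a, a) == pytest.approx(0.0)

    def test_orthogonal_is_one(self):
        a = self._vec([1] + [0] * 8)
        b = self._vec([0, 1] + [0] * 7)
        assert color_distance(a, b) == pytest.approx(1.0)

    def test_scale_invariance(self):
        a = self._vec(np.arange(1, 10))
        b = self._vec(2 * np.arange(1, 10))
        assert color_distance(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_zero_norm_guarded(self):
        a = self._vec(np.zeros(9))
        with pytest.raises(ValueError):
            color_distance(a, a)


class TestQuantize:
    def test_identity_at_full_depth(self, rng):
        ch = rng.integers(0, 256, size=(6, 6))
        assert np.array_equal(quantize_channel(ch, 256), ch)

    def test_two_levels(self):
        assert quantize_channel(np.array([0, 255]), 2).tolist() == [0, 1]

    def test_uniform_binning(self):
        out = quantize_channel(np.array([0, 100, 200]), 8)
        assert out.tolist() == [0, 3, 6]


class TestComputeCM:
    def test_constant_region_single_entry(self):
        q = np.full((5, 5), 3)
        mask = np.ones((5, 5), dtype=bool)
        for angle in ANGLES:
            P = compute_cm(q, mask, 8, angle)
            assert P[3, 3] == pytest.approx(1.0)
            assert P.sum() == pytest.approx(1.0)

    def test_alternating_columns_symmetric(self):
        # columns 0,1,0,1: 12 ordered horizontal pairs; symmetric counting
        # balances the two transition directions
        q = np.tile([0, 1, 0, 1], (4, 1))
        mask = np.ones((4, 4), dtype=bool)
        P = compute_cm(q, mask, 2, 0, symmetric=True)
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)

    def test_alternating_columns_directed(self):
        # one-directional counting sees 0->1 twice per row, 1->0 once
        q = np.tile([0, 1, 0, 1], (4, 1))
        mask = np.ones((4, 4), dtype=bool)
        P = compute_cm(q, mask, 2, 0, symmetric=False)
        assert P[0, 1] == pytest.approx(8 / 12)
        assert P[1, 0] == pytest.approx(4 / 12)

    @pytest.mark.parametrize("angle", ANGLES)
    @pytest.mark.parametrize("symmetric", [True, False])
    def test_matches_brute_force_on_random_masks(self, rng, angle, symmetric):
        for _ in range(25):
            h, w = rng.integers(3, 17, size=2)
            q = rng.integers(0, 8, size=(h, w))
            mask = rng.random((h, w)) < 0.75
            expected = brute_force_cm(q, mask, 8, angle, 1, symmetric)
            if expected is None:
                with pytest.raises(NoPairsError):
                    compute_cm(q, mask, 8, angle, 1, symmetric)
            else:
                P = compute_cm(q, mask, 8, angle, 1, symmetric)
                assert np.allclose(P, expected)

    def test_mask_restricts_pairs(self):
        q = np.arange(16).reshape(4, 4) % 4
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[0, 1] = True
        P = compute_cm(q, mask, 4, 0)
        assert P.sum() == pytest.approx(1.0)
        assert P[q[0, 0], q[0, 1]] > 0

    def test_no_pairs_raises(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = True
        with pytest.raises(NoPairsError):
            compute_cm(np.zeros((4, 4), dtype=int), mask, 2, 0)


class TestCMFeatures:
    def test_constant_region(self):
        P = np.zeros((8, 8))
        P[3, 3] = 1.0
        f = cm_features(P)
        assert f.contrast == 0 and f.energy == 1 and f.homogeneity == 1
        assert f.correlation_degenerate and f.correlation == 0

    def test_checkerboard_hand_values(self):
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = cm_features(P)
        assert f.contrast == pytest.approx(1.0)
        assert f.energy == pytest.approx(0.5)
        assert f.homogeneity == pytest.approx(0.5)
        assert f.correlation == pytest.approx(-1.0)

    def test_uniform_matrix_energy(self):
        P = np.full((2, 2), 0.25)
        assert cm_features(P).energy == pytest.approx(0.25)


class TestTextureDescriptor:
    def test_constant_region(self):
        frame = np.full((10, 10, 3), 80, dtype=np.uint8)
        mask = np.ones((10, 10), dtype=bool)
        d = texture_descriptor(frame, mask)
        assert np.allclose(d.values[..., 0], 0)  # contrast
        assert np.allclose(d.values[..., 2], 1)  # energy
        assert np.allclose(d.values[..., 3], 1)  # homogeneity

    def test_bounds_hold(self, textured_crop):
        crop, mask = textured_crop
        d = texture_descriptor(crop, mask)
        con, corr, eng, hom = (d.values[..., i] for i in range(4))
        assert (con >= 0).all()
        assert ((eng > 0) & (eng <= 1)).all()
        assert ((hom > 0) & (hom <= 1)).all()
        assert ((corr >= -1 - 1e-12) & (corr <= 1 + 1e-12)).all()


class TestTextureDistance:
    def test_self_distance_zero(self, textured_crop):
        crop, mask = textured_crop
        d = texture_descriptor(crop, mask)
        assert np.allclose(texture_distance(d, d), 0)

    def test_rotation_invariance(self, textured_crop):
        crop, mask = textured_crop
        a = texture_descriptor(crop, mask)
        b = texture_descriptor(np.rot90(crop).copy(), np.rot90(mask).copy())
        assert np.nanmax(texture_distance(a, b)) == pytest.approx(0, abs=1e-9)

    def test_minimum_over_angle_pairs(self):
        # single feature across angles: a={1,2,3,4}, b={5,2.5,9,9} -> 0.5
        params = CMParams()
        va = np.zeros((1, 4, 4))
        vb = np.zeros((1, 4, 4))
        va[0, :, 0] = [1, 2, 3, 4]
        vb[0, :, 0] = [5, 2.5, 9, 9]
        valid = np.ones((1, 4), dtype=bool)
        a = TextureDescriptor(va, valid, params)
        b = TextureDescriptor(vb, valid, params)
        assert texture_distance(a, b)[0, 0] == pytest.approx(0.5)

    def test_mismatched_params_rejected(self, textured_crop):
        crop, mask = textured_crop
        a = texture_descriptor(crop, mask, CMParams(levels=8))
        b = texture_descriptor(crop, mask, CMParams(levels=16))
        with pytest.raises(ValueError):
            texture_distance(a, b)

    def test_thin_mask_angles_dropped_not_fatal(self):
        frame = np.zeros((1, 6, 3), dtype=np.uint8)
        frame[0, ::2] = 200
        mask = np.ones((1, 6), dtype=bool)  # one row: only 0-degree pairs
        d = texture_descriptor(frame, mask)
        assert d.valid[:, 0].all()
        assert not d.valid[:, 1:].any()
        t = texture_distance(d, d)
        assert np.allclose(t[~np.isnan(t)], 0)


class TestCentroidDistance:
    def test_pythagorean(self):
        assert centroid_distance((0, 0), (0, 0)) == 0
        assert centroid_distance((0, 0), (3, 4)) == 5

    @given(st.tuples(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)),
           st.tuples(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)))
    def test_symmetric_nonnegative(self, a, b):
        assert centroid_distance(a, b) >= 0
        assert centroid_distance(a, b) == centroid_distance(b, a)
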