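import numpy as np
import pytest

from carotidseg.metrics import iou
from carotidseg.records import MaskRecord
from carotidseg.self_training import (SelfTrainConfig, accept_or_revert,
                                      clip_to_bbox, ensemble_predict,
                                      erode_disk1, split_sides, update_masks)


def brute_force_erode(mask, eight_connected=False):
    """Naive pixel-loop erosion oracle; outside-image counts as background."""
    m = np.asarray(mask).astype(bool)
    h, w = m.shape
    if eight_connected:
        offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)]
    else:
        offsets = [(0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)]
    out = np.zeros_like(m)
    for i in range(h):
        for j in range(w):
            ok = True
            for di, dj in offsets:
                ii, jj = i + di, j + dj
                if not (0 <= ii < h and 0 <= jj < w) or not m[ii, jj]:
                    ok = False
                    break
            out[i, j] = ok
    return out.astype(np.uint8)


def brute_force_side_iou(a, b):
    inter = sum(1 for x, y in zip(a.ravel(), b.ravel()) if x and y)
    union = sum(1 for x, y in zip(a.ravel(), b.ravel()) if x or y)
    return 1.0 if union == 0 else inter / union


def brute_force_update(pred, bbox, round_idx, erosion_rounds=4, gate=0.5):
    """Independent composition of the four mask-update steps."""
    m = np.asarray(pred).astype(np.uint8)
    if round_idx < erosion_rounds:
        m = brute_force_erode(m)
    c = m.shape[1] // 2
    halves = []
    for sl in (slice(0, c), slice(c, None)):
        p_half, b_half = m[:, sl], np.asarray(bbox)[:, sl]
        if brute_force_side_iou(p_half, b_half) >= gate:
            halves.append(p_half)
        else:
            halves.append(b_half.astype(np.uint8))
    full = np.concatenate(halves, axis=1)
    return (full.astype(bool) & np.asarray(bbox).astype(bool)).astype(np.uint8)


class FakeNet:
    """Inference stub returning a fixed probability map."""

    def __init__(self, prob, shape=(16, 16)):
        self.prob = np.broadcast_to(np.asarray(prob, dtype=float), shape)

        class _Cfg:
            in_shape = (shape[0], shape[1], 3)
        self.cfg = _Cfg()

    def forward(self, x, train=False):
        n = x.shape[0]
        return np.broadcast_to(self.prob, (n, 1) + self.prob.shape).copy()


def _slice(shape=(16, 16)):
    from carotidseg.pseudo_rgb import PseudoRGBSlice
    return PseudoRGBSlice(data=np.zeros(shape + (3,)), slice_index=0)


class TestEnsemblePredict:
    def test_mean_of_equal_nets_equals_single(self):
        nets = [FakeNet(0.7) for _ in range(5)]
        out = ensemble_predict(nets, _slice())
        assert (out == 1).all()

    @pytest.mark.parametrize("probs,expected", [
        ((0.4, 0.4, 0.4, 0.9, 0.9), 1),   # mean 0.6
        ((0.4, 0.4, 0.4, 0.4, 0.9), 1),   # mean 0.5: the ≥ convention
        ((0.4, 0.4, 0.4, 0.4, 0.4), 0),   # mean 0.4
    ])
    def test_mean_then_threshold(self, probs, expected):
        nets = [FakeNet(p) for p in probs]
        out = ensemble_predict(nets, _slice())
        assert (out == expected).all()

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            ensemble_predict([], _slice())


class TestErode:
    def test_solid_3x3_block_leaves_center(self):
        m = np.zeros((7, 7), dtype=np.uint8)
        m[2:5, 2:5] = 1
        out = erode_disk1(m)
        expected = np.zeros_like(m)
        expected[3, 3] = 1
        np.testing.assert_array_equal(out, expected)

    def test_isolated_pixel_vanishes(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[2, 2] = 1
        assert erode_disk1(m).sum() == 0

    def test_all_ones_erodes_border(self):
        m = np.ones((6, 8), dtype=np.uint8)
        out = erode_disk1(m)
        np.testing.assert_array_equal(out, brute_force_erode(m))
        assert out[0].sum() == 0 and out[:, -1].sum() == 0
        assert out[1:-1, 1:-1].all()

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(20):
            m = (rng.random((9, 11)) > 0.4).astype(np.uint8)
            np.testing.assert_array_equal(erode_disk1(m), brute_force_erode(m))
            np.testing.assert_array_equal(
                erode_disk1(m, eight_connected=True),
                brute_force_erode(m, eight_connected=True))


class TestSplitSides:
    def test_even_split_widths(self):
        left, right = split_sides(np.zeros((10, 240)))
        assert left.shape == (10, 120) and right.shape == (10, 120)

    def test_concat_reproduces_input(self, rng):
        m = (rng.random((8, 11)) > 0.5).astype(np.uint8)
        left, right = split_sides(m)
        np.testing.assert_array_equal(np.concatenate([left, right], axis=1), m)

    def test_left_only_mask(self):
        m = np.zeros((6, 10), dtype=np.uint8)
        m[:, :3] = 1
        _, right = split_sides(m)
        assert right.sum() == 0


class TestAcceptOrRevert:
    def _bbox(self):
        b = np.zeros((8, 8), dtype=np.uint8)
        b[2:4, 0:2] = 1   # left side: 4 px
        b[2:4, 6:8] = 1   # right side: 4 px
        return b

    def test_accept_above_gate(self):
        bbox = self._bbox()
        pred = np.zeros_like(bbox)
        pred[2:4, 0:2] = 1
        pred[2, 0] = 0                      # 3 of 4 left px: IoU 0.75
        pred[2:4, 6:8] = 1                  # right perfect
        out, flags = accept_or_revert(pred, bbox, 0.5)
        assert flags == (True, True)
        np.testing.assert_array_equal(out, pred)

    def test_revert_below_gate(self):
        bbox = self._bbox()
        pred = np.zeros_like(bbox)
        pred[2, 6] = 1                       # 1 of 4 right px: IoU 0.25
        out, flags = accept_or_revert(pred, bbox, 0.5)
        assert flags == (False, False)
        np.testing.assert_array_equal(out, bbox)

    def test_identity_prediction_accepted(self):
        bbox = self._bbox()
        out, flags = accept_or_revert(bbox, bbox, 0.5)
        assert flags == (True, True)
        np.testing.assert_array_equal(out, bbox)

    def test_empty_empty_side_accepted(self):
        bbox = np.zeros((6, 6), dtype=np.uint8)
        bbox[1:3, 4:6] = 1
        pred = bbox.copy()
        out, flags = accept_or_revert(pred, bbox, 0.5)
        assert flags == (True, True)    # left side both-empty counts as IoU 1

    def test_pred_nonempty_on_empty_bbox_side_reverts(self):
        bbox = np.zeros((6, 6), dtype=np.uint8)
        pred = np.zeros_like(bbox)
        pred[2, 1] = 1
        out, flags = accept_or_revert(pred, bbox, 0.5)
        assert flags == (False, True)
        assert out.sum() == 0


class TestClip:
    def test_outside_pixels_erased(self):
        bbox = np.zeros((5, 5), dtype=np.uint8)
        bbox[1:4, 1:4] = 1
        mask = np.ones((5, 5), dtype=np.uint8)
        np.testing.assert_array_equal(clip_to_bbox(mask, bbox), bbox)

    def test_subset_unchanged(self):
        bbox = np.ones((4, 4), dtype=np.uint8)
        mask = np.zeros_like(bbox)
        mask[1, 1] = 1
        np.testing.assert_array_equal(clip_to_bbox(mask, bbox), mask)

    def test_empty_bbox_annihilates(self):
        mask = np.ones((4, 4), dtype=np.uint8)
        assert clip_to_bbox(mask, np.zeros_like(mask)).sum() == 0


class TestUpdateMasks:
    def _pairs_and_bboxes(self, rng, n=4, shape=(16, 16)):
        from carotidseg.pseudo_rgb import PseudoRGBSlice, SlicePair
        pairs, bboxes = [], []
        for _ in range(n):
            img = rng.random(shape + (3,))
            bbox = np.zeros(shape, dtype=np.uint8)
            r, c = rng.integers(2, shape[0] - 6, 2)
            bbox[r:r + 4, c:c + 4] = 1
            pairs.append(SlicePair(image=PseudoRGBSlice(data=img, slice_index=0),
                                   mask=MaskRecord(mask=bbox)))
            bboxes.append(bbox)
        return pairs, bboxes

    def test_erosion_only_in_early_rounds(self, rng):
        pairs, bboxes = self._pairs_and_bboxes(rng)
        nets = [FakeNet(1.0) for _ in range(5)]      # predict everything
        cfg = SelfTrainConfig()
        early = update_masks(nets, pairs, bboxes, 0, cfg)
        late = update_masks(nets, pairs, bboxes, 4, cfg)
        for e, l, b in zip(early, late, bboxes):
            # all-ones prediction eroded loses the border, then both are
            # gated/clipped against the same bbox
            np.testing.assert_array_equal(
                e.mask, brute_force_update(np.ones_like(b), b, 0))
            np.testing.assert_array_equal(
                l.mask, brute_force_update(np.ones_like(b), b, 4))

    def test_all_background_prediction_reverts_to_bbox(self, rng):
        pairs, bboxes = self._pairs_and_bboxes(rng)
        nets = [FakeNet(0.0) for _ in range(5)]
        records = update_masks(nets, pairs, bboxes, 0, SelfTrainConfig())
        for rec, bbox in zip(records, bboxes):
            np.testing.assert_array_equal(rec.mask, bbox)

    def test_output_always_inside_bbox(self, rng):
        pairs, bboxes = self._pairs_and_bboxes(rng)
        nets = [FakeNet((rng.random((16, 16)) > 0.3).astype(float))
                for _ in range(5)]
        for r in range(7):
            for rec, bbox in zip(update_masks(nets, pairs, bboxes, r), bboxes):
                assert not (rec.mask.astype(bool) & ~bbox.astype(bool)).any()

    def test_provenance_and_round_recorded(self, rng):
        pairs, bboxes = self._pairs_and_bboxes(rng)
        nets = [FakeNet(0.0) for _ in range(5)]
        records = update_masks(nets, pairs, bboxes, 2, SelfTrainConfig())
        assert all(r.provenance == "refined" and r.round == 2 for r in records)

    def test_matches_brute_force_oracle_on_random_fixtures(self, rng):
        """The vectorized update equals a naive pixel-loop composition of
        erode → per-side IoU gate → clip on random ≤16×16 instances."""
        from carotidseg.pseudo_rgb import PseudoRGBSlice, SlicePair
        for trial in range(25):
            h = int(rng.integers(6, 17))
            w = int(rng.integers(6, 17))
            prob = (rng.random((h, w)) > 0.5).astype(float)
            bbox = (rng.random((h, w)) > 0.6).astype(np.uint8)
            round_idx = int(rng.integers(0, 7))
            pair = SlicePair(
                image=PseudoRGBSlice(data=rng.random((h, w, 3)), slice_index=0),
                mask=MaskRecord(mask=bbox))
            nets = [FakeNet(prob, shape=(h, w)) for _ in range(5)]
            got = update_masks(nets, [pair], [bbox], round_idx,
                               SelfTrainConfig())[0].mask
            expected = brute_force_update(prob, bbox, round_idx)
            np.testing.assert_array_equal(got, expected)
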