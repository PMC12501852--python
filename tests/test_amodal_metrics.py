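"""Evaluation statistics: pixel F1, Hungarian F@.75, mIoU, AP."""

import itertools

import numpy as np
import pytest

from amodalfruit import amodal_metrics as am
from amodalfruit.amodal_masks import InstanceMasks


def _mask(shape, sl):
    m = np.zeros(shape, bool)
    m[sl] = True
    return m


class TestPixelF1:
    def test_identical_masks(self):
        m = _mask((10, 10), np.s_[2:7, 2:7])
        assert am.pixel_f1(m, m) == 1.0

    def test_disjoint_masks(self):
        a = _mask((10, 10), np.s_[0:3, 0:3])
        b = _mask((10, 10), np.s_[5:8, 5:8])
        assert am.pixel_f1(a, b) == 0.0

    def test_half_overlap(self):
        # |a| = |b| = 100, |intersection| = 50 -> F1 = 0.5
        a = _mask((20, 20), np.s_[0:10, 0:10])
        b = _mask((20, 20), np.s_[5:15, 0:10])
        assert am.pixel_f1(a, b) == pytest.approx(0.5)

    def test_empty_vs_empty_is_perfect(self):
        z = np.zeros((5, 5), bool)
        assert am.pixel_f1(z, z) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            am.pixel_f1(np.ones((3, 3), bool), np.ones((4, 4), bool))


def brute_force_best_assignment(f1: np.ndarray) -> float:
    """Max total F1 over all one-to-one assignments, by enumeration."""
    P, G = f1.shape
    best = 0.0
    k = min(P, G)
    rows = range(P)
    for pr in itertools.permutations(rows, k):
        for cols in itertools.permutations(range(G), k):
            best = max(best, sum(f1[i, j] for i, j in zip(pr, cols)))
    return best


class TestHungarianMatching:
    def test_adversarial_2x2_beats_greedy(self):
        """Greedy takes the 0.8 pair and strands the second gt (F@.75 =
        0.5); the optimal assignment pairs (1,2) and (2,1), total 1.53,
        both above threshold, giving 1.0."""
        from scipy.optimize import linear_sum_assignment
        f1 = np.array([[0.80, 0.76], [0.77, 0.00]])
        rows, cols = linear_sum_assignment(-f1)
        pairs = list(zip(rows.tolist(), cols.tolist()))
        total = sum(f1[i, j] for i, j in pairs)
        assert total == pytest.approx(1.53)
        hits = sum(1 for i, j in pairs if f1[i, j] >= 0.75)
        assert hits / 2 == 1.0
        # greedy-by-best for contrast
        greedy_pairs = [(0, 0), (1, 1)]
        greedy_hits = sum(1 for i, j in greedy_pairs if f1[i, j] >= 0.75)
        assert greedy_hits / 2 == 0.5

    def test_matches_exhaustive_enumeration(self, rng):
        from scipy.optimize import linear_sum_assignment
        for _ in range(200):
            P = int(rng.integers(1, 6))
            G = int(rng.integers(1, 6))
            f1 = rng.uniform(size=(P, G))
            rows, cols = linear_sum_assignment(-f1)
            total = float(f1[rows, cols].sum())
            assert total == pytest.approx(brute_force_best_assignment(f1))


class TestFAt075:
    def test_singleton_perfect(self):
        m = _mask((10, 10), np.s_[2:8, 2:8])
        assert am.f_at_075([m], [m]) == 1.0

    def test_unmatched_gt_halves_score(self):
        g1 = _mask((20, 20), np.s_[0:10, 0:10])
        g2 = _mask((20, 20), np.s_[12:18, 12:18])
        # one prediction overlapping g1 with F1 = 0.8:
        # |p| = 100, |inter| = 80 -> F1 = 160/200 = 0.8
        p = _mask((20, 20), np.s_[0:10, 0:10]).copy()
        p[0:2, 0:10] = False
        p[10:12, 0:10] = True
        assert am.pixel_f1(p, g1) == pytest.approx(0.8)
        assert am.f_at_075([p], [g1, g2]) == 0.5

    def test_no_gts_undefined(self):
        with pytest.raises(am.UndefinedMetricError):
            am.f_at_075([_mask((5, 5), np.s_[0:2, 0:2])], [])


class TestMIoU:
    def test_perfect_predictions(self):
        masks = [_mask((15, 15), np.s_[0:5, 0:5]),
                 _mask((15, 15), np.s_[8:13, 8:13])]
        assert am.miou(masks, masks) == 1.0

    def test_single_pair_third(self):
        # |inter| = 50, |union| = 150 -> IoU = 1/3
        a = _mask((20, 20), np.s_[0:10, 0:10])
        b = _mask((20, 20), np.s_[5:15, 0:10])
        assert am.mask_iou(a, b) == pytest.approx(1 / 3)
        assert am.miou([a], [b]) == pytest.approx(1 / 3)

    def test_unmatched_gt_counts_zero(self):
        g1 = _mask((20, 20), np.s_[0:10, 0:10])
        g2 = _mask((20, 20), np.s_[12:18, 12:18])
        p = _mask((20, 20), np.s_[0:10, 0:10]).copy()
        p[8:10, 0:10] = False
        p[10:12, 0:5] = True     # IoU vs g1 = 0.8 exactly? check numerically
        iou = am.mask_iou(p, g1)
        assert am.miou([p], [g1, g2]) == pytest.approx(iou / 2)

    def test_semantic_mode_includes_background(self):
        m = _mask((10, 10), np.s_[0:5, 0:5])
        assert am.miou([m], [m], mode="semantic") == 1.0


class TestAveragePrecision:
    def test_single_correct_detection(self):
        g = _mask((20, 20), np.s_[2:12, 2:12])
        p = g.copy()
        p[2:3, 2:12] = False     # IoU = 90/100 = 0.9
        assert am.mask_iou(p, g) == pytest.approx(0.9)
        assert am.average_precision([(p, 0.9)], [g], 0.5) == 1.0

    def test_spurious_detection_order_matters(self):
        g = _mask((20, 20), np.s_[2:12, 2:12])
        spurious = _mask((20, 20), np.s_[15:19, 15:19])
        correct_first = [(g, 0.9), (spurious, 0.8)]
        assert am.average_precision(correct_first, [g], 0.5) == 1.0
        spurious_first = [(g, 0.8), (spurious, 0.9)]
        assert am.average_precision(spurious_first, [g], 0.5) == \
            pytest.approx(0.5, abs=0.01)

    def test_mean_ap(self):
        assert am.mean_ap([0.8, 0.6]) == pytest.approx(0.7)


class TestInvariants:
    def _random_sets(self, rng, n=6):
        masks = []
        for _ in range(n):
            m = np.zeros((24, 24), bool)
            r0, c0 = rng.integers(0, 14, 2)
            m[r0:r0 + rng.integers(4, 10), c0:c0 + rng.integers(4, 10)] = True
            masks.append(m)
        return masks

    def test_permutation_invariance(self, rng):
        gts = self._random_sets(rng, 4)
        preds = self._random_sets(rng, 5)
        base_f = am.f_at_075(preds, gts)
        base_m = am.miou(preds, gts)
        for _ in range(5):
            p = [preds[i] for i in rng.permutation(5)]
            g = [gts[i] for i in rng.permutation(4)]
            assert am.f_at_075(p, g) == pytest.approx(base_f)
            assert am.miou(p, g) == pytest.approx(base_m)

    def test_spurious_low_score_pred_never_raises_ap(self, rng):
        gts = self._random_sets(rng, 3)
        preds = [(m, 0.9 - 0.1 * i) for i, m in
                 enumerate(self._random_sets(rng, 3))]
        junk = np.zeros((24, 24), bool)
        junk[0:2, 0:2] = True
        for thr in (0.5, 0.75):
            ap = am.average_precision(preds, gts, thr)
            ap_junk = am.average_precision(preds + [(junk, 0.01)], gts, thr)
            assert ap_junk <= ap + 1e-12

    def test_removing_unmatched_gt_never_lowers_f(self, rng):
        gts = self._random_sets(rng, 3)
        preds = gts[:2]
        far = np.zeros((24, 24), bool)
        far[22:24, 22:24] = True
        with_extra = am.f_at_075(preds, gts + [far])
        without = am.f_at_075(preds, gts)
        assert without >= with_extra

    def test_all_statistics_bounded(self, rng):
        for _ in range(10):
            gts = self._random_sets(rng, int(rng.integers(1, 5)))
            preds = self._random_sets(rng, int(rng.integers(0, 5)))
            assert 0.0 <= am.f_at_075(preds, gts) <= 1.0
            assert 0.0 <= am.miou(preds, gts) <= 1.0
            scored = [(m, float(rng.uniform())) for m in preds]
            if preds:
                assert 0.0 <= am.average_precision(scored, gts, 0.5) <= 1.0


def test_self_evaluation_is_perfect(rng):
    """Ground truth evaluated against itself scores 1.0 everywhere."""
    gts = []
    for k in range(4):
        amod = np.zeros((32, 32), bool)
        amod[2 + 6 * k: 8 + 6 * k, 3:12] = True
        vis = amod.copy()
        vis[:, 3:5] &= k % 2 == 0
        gts.append(InstanceMasks(amodal=amod, visible=vis))
    preds = [{"amodal": g.amodal, "visible": g.visible, "score": 1.0}
             for g in gts]
    rep = am.evaluate_frame(preds, gts)
    assert rep.f_at_075 == 1.0
    assert rep.miou == 1.0
    assert rep.ap50 == rep.ap75 == rep.map == 1.0
    assert rep.precision == rep.recall == rep.f1 == 1.0
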