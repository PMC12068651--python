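"""Metric oracles: AUC by pair enumeration, confusion counting, localization
precision, random-box baseline, consensus masks and patch-level dice."""

import numpy as np
import pytest

from sparsebagnet.evaluation import (
    AlignmentError,
    classification_metrics,
    consensus_masks,
    localization_precision,
    patch_dice,
    random_box_baseline,
)
from sparsebagnet.explanation import BoundingBox, ExplanationSet


def _expl(boxes, image_id="img"):
    return ExplanationSet(image_id=image_id, boxes=boxes)


def _box(row, col, score=1.0, rank=1, side=33):
    return BoundingBox(row=row, col=col, side=side, score=score, rank=rank)


class TestClassificationMetrics:
    def test_perfect_classifier(self):
        labels = [0, 0, 1, 1]
        scores = [0.1, 0.2, 0.8, 0.9]
        rep = classification_metrics(labels, scores, n_bootstrap=200, seed=0)
        assert rep.auc.point == 1.0
        assert rep.accuracy.point == 1.0
        assert rep.auc.ci_low == rep.auc.ci_high == 1.0

    def test_four_point_toy_auc_by_pair_enumeration(self):
        labels = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.4, 0.6, 0.1])
        rep = classification_metrics(labels, scores, n_bootstrap=50, seed=0)
        # oracle: fraction of (positive, negative) pairs ranked correctly
        pairs = [(p, n) for p in scores[labels == 1] for n in scores[labels == 0]]
        auc = np.mean([1.0 if p > n else 0.5 if p == n else 0.0 for p, n in pairs])
        assert auc == 0.75
        assert np.isclose(rep.auc.point, 0.75)

    def test_confusion_counting_oracle(self):
        # TP=3, FN=1, TN=4, FP=2 at threshold 0.5
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.6, 0.7, 0.1, 0.2, 0.3, 0.4])
        rep = classification_metrics(labels, scores, n_bootstrap=50, seed=0)
        assert np.isclose(rep.sensitivity.point, 0.75)
        assert np.isclose(rep.specificity.point, 2 / 3)
        assert np.isclose(rep.precision.point, 0.6)
        assert np.isclose(rep.accuracy.point, 0.7)

    def test_single_class_auc_undefined_others_reported(self):
        rep = classification_metrics([1, 1, 1], [0.9, 0.8, 0.7], n_bootstrap=20, seed=0)
        assert rep.auc is None
        assert rep.accuracy.point == 1.0
        assert rep.sensitivity.point == 1.0

    def test_ci_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(0)

        def width(n):
            labels = rng.integers(0, 2, n)
            scores = np.clip(labels * 0.4 + rng.uniform(0, 0.6, n), 0, 1)
            rep = classification_metrics(labels, scores, n_bootstrap=300, seed=1)
            return rep.accuracy.ci_high - rep.accuracy.ci_low

        assert width(500) < width(50)

    def test_point_estimate_inside_ci(self):
        rng = np.random.default_rng(2)
        inside = 0
        for seed in range(20):
            labels = rng.integers(0, 2, 80)
            scores = np.clip(labels * 0.3 + rng.uniform(0, 0.7, 80), 0, 1)
            rep = classification_metrics(labels, scores, n_bootstrap=200, seed=seed)
            if rep.accuracy.ci_low <= rep.accuracy.point <= rep.accuracy.ci_high:
                inside += 1
        assert inside >= 19


class TestLocalizationPrecision:
    def test_all_boxes_hit(self):
        mask = np.ones((128, 128), bool)
        expl = _expl([_box(0, 0), _box(40, 40, rank=2)])
        pooled, frame = localization_precision([expl], [mask])
        assert pooled == 1.0

    def test_empty_masks_give_zero(self):
        mask = np.zeros((128, 128), bool)
        expl = _expl([_box(0, 0)])
        pooled, _ = localization_precision([expl], [mask])
        assert pooled == 0.0

    def test_three_of_four_boxes_hit(self):
        mask = np.zeros((200, 200), bool)
        mask[10, 10] = mask[60, 60] = mask[110, 110] = True
        boxes = [
            _box(0, 0, rank=1),      # hit (10,10)
            _box(50, 50, rank=2),    # hit (60,60)
            _box(100, 100, rank=3),  # hit (110,110)
            _box(160, 160, rank=4),  # miss
        ]
        pooled, frame = localization_precision([_expl(boxes)], [mask])
        # oracle: exhaustive per-box pixel scan
        hits = sum(mask[b.row : b.row + 33, b.col : b.col + 33].any() for b in boxes)
        assert hits == 3
        assert pooled == 0.75
        assert frame.n_hits.iloc[0] == 3

    def test_zero_box_images_excluded_from_denominator(self):
        mask = np.ones((64, 64), bool)
        pooled, frame = localization_precision(
            [_expl([]), _expl([_box(0, 0)])], [mask, mask]
        )
        assert pooled == 1.0
        assert np.isnan(frame.precision.iloc[0])

    def test_box_order_invariance(self):
        mask = np.zeros((128, 128), bool)
        mask[20, 20] = True
        boxes = [_box(0, 0, rank=1), _box(80, 80, rank=2)]
        a, _ = localization_precision([_expl(boxes)], [mask])
        b, _ = localization_precision([_expl(boxes[::-1])], [mask])
        assert a == b


class TestRandomBoxBaseline:
    def _scene(self, mask_half=False):
        img = np.zeros((128, 128, 3), np.float32)
        rr, cc = np.mgrid[0:128, 0:128]
        disc = (rr - 64) ** 2 + (cc - 64) ** 2 <= 60**2
        img[disc] = 0.6
        mask = np.zeros((128, 128), bool)
        if mask_half:
            mask[disc & (cc < 64)] = True
        return img, mask, disc

    def test_saturated_mask_gives_one(self):
        img, _, disc = self._scene()
        pooled = random_box_baseline(img, disc, n_boxes=10, seed=0)
        assert pooled == 1.0

    def test_empty_mask_gives_zero(self):
        img, mask, _ = self._scene()
        assert random_box_baseline(img, mask, n_boxes=10, seed=0) == 0.0

    def test_half_mask_matches_areal_fraction(self):
        """With the mask covering one half of the disc, the hit rate over
        many random boxes must sit within 3 binomial SEs of the hit
        probability computed by exhaustively scanning every acceptable
        box position."""
        img, mask, _ = self._scene(mask_half=True)
        black = (img < 10 / 255).all(axis=2)
        hits = total = 0
        for r in range(0, 96, 2):  # exhaustive areal oracle on a sublattice
            for c in range(0, 96, 2):
                if black[r : r + 33, c : c + 33].mean() <= 0.10:
                    total += 1
                    hits += mask[r : r + 33, c : c + 33].any()
        p_true = hits / total
        n = 400
        est = random_box_baseline(img, mask, n_boxes=n, seed=1)
        se = np.sqrt(p_true * (1 - p_true) / n)
        assert abs(est - p_true) <= 3 * se + 0.02

    def test_black_image_exhausts(self):
        from sparsebagnet.evaluation import SamplingExhaustionError

        img = np.zeros((64, 64, 3), np.float32)
        with pytest.raises(SamplingExhaustionError):
            random_box_baseline(img, np.zeros((64, 64), bool), n_boxes=5, seed=0,
                                max_attempts=50)


class TestConsensusMasks:
    def test_identical_masks(self):
        m = np.random.default_rng(0).uniform(0, 1, (32, 32)) > 0.7
        union, inter = consensus_masks([m, m.copy()])
        assert (union == m).all() and (inter == m).all()

    def test_disjoint_masks(self):
        a = np.zeros((16, 16), bool)
        b = np.zeros((16, 16), bool)
        a[:4], b[8:] = True, True
        union, inter = consensus_masks([a, b])
        assert inter.sum() == 0
        assert union.sum() == a.sum() + b.sum()

    def test_nesting_of_counts(self):
        rng = np.random.default_rng(1)
        masks = [rng.uniform(0, 1, (24, 24)) > 0.6 for _ in range(3)]
        union, inter = consensus_masks(masks)
        for m in masks:
            assert inter.sum() <= m.sum() <= union.sum()
        assert (inter <= union).all()

    def test_size_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            consensus_masks([np.zeros((4, 4), bool), np.zeros((5, 5), bool)])


class TestPatchDice:
    def test_identity_is_one(self):
        m = np.zeros((128, 128), bool)
        m[30:40, 50:60] = True
        assert patch_dice(m, m, stride=8) == 1.0

    def test_disjoint_positive_patches_zero(self):
        a = np.zeros((128, 128), bool)
        b = np.zeros((128, 128), bool)
        a[0:2, 0:2] = True
        b[90:92, 90:92] = True
        assert patch_dice(a, b, stride=33) == 0.0

    def test_both_empty_defined_as_one(self):
        z = np.zeros((64, 64), bool)
        assert patch_dice(z, z) == 1.0

    @pytest.mark.parametrize("stride", [8, 32, 33])
    def test_lattice_enumeration_oracle(self, stride):
        """Two single-pixel masks 20 px apart, scored per lattice: compare
        against a brute-force enumeration of every patch placement."""
        a = np.zeros((128, 128), bool)
        b = np.zeros((128, 128), bool)
        a[60, 50] = True
        b[60, 70] = True

        def positive(mask):
            pos = set()
            for i, r in enumerate(range(0, 128 - 33 + 1, stride)):
                for j, c in enumerate(range(0, 128 - 33 + 1, stride)):
                    if mask[r : r + 33, c : c + 33].any():
                        pos.add((i, j))
            return pos

        pa, pb = positive(a), positive(b)
        expected = 2 * len(pa & pb) / (len(pa) + len(pb)) if (pa or pb) else 1.0
        assert np.isclose(patch_dice(a, b, stride=stride), expected)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 1, (100, 100)) > 0.95
        b = rng.uniform(0, 1, (100, 100)) > 0.95
        assert patch_dice(a, b) == patch_dice(b, a)

    def test_bad_stride_rejected(self):
        with pytest.raises(ValueError):
            patch_dice(np.zeros((64, 64), bool), np.zeros((64, 64), bool), stride=0)
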