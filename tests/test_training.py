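"""Sparse objective, subject-grouped splitting, schedule and the lambda rule."""

import numpy as np
import pandas as pd
import pytest

from sparsebagnet.model import build_reduced_backbone
from sparsebagnet.training import (
    AugmentationConfig,
    TrainConfig,
    cosine_lr,
    select_lambda,
    sparse_loss,
    sparse_loss_grad,
    split_by_subject,
    train,
)


class TestSparseLoss:
    def test_lambda_zero_is_pure_cross_entropy(self):
        rng = np.random.default_rng(0)
        ev = rng.normal(0, 1, (4, 2, 3, 3))
        labels = np.array([0, 1, 1, 0])
        total, ce, l1 = sparse_loss(ev, labels, 0.0)
        assert total == ce
        assert l1 > 0  # reported but unweighted

    def test_hand_computed_worked_example(self):
        """1x1 maps A_0 = 0.5, A_1 = -0.5, label 0, lambda 0.1:
        CE = -log(e^0.5 / (e^0.5 + e^-0.5)) ~ 0.3133, l1 = 1.0."""
        ev = np.array([[[[0.5]], [[-0.5]]]])
        total, ce, l1 = sparse_loss(ev, np.array([0]), 0.1)
        expected_ce = -np.log(np.exp(0.5) / (np.exp(0.5) + np.exp(-0.5)))
        assert np.isclose(ce, expected_ce, atol=1e-4)
        assert np.isclose(ce, 0.3133, atol=1e-4)
        assert np.isclose(l1, 1.0)
        assert np.isclose(total, ce + 0.1)

    def test_l1_homogeneity(self):
        rng = np.random.default_rng(1)
        ev = rng.normal(0, 1, (3, 2, 4, 4))
        labels = np.array([1, 0, 1])
        _, _, l1 = sparse_loss(ev, labels, 0.5)
        _, _, l1x2 = sparse_loss(2 * ev, labels, 0.5)
        assert np.isclose(l1x2, 2 * l1)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            sparse_loss(np.zeros((1, 2, 1, 1)), np.array([0]), -0.1)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        ev = rng.normal(0, 1, (2, 2, 2, 2))
        labels = np.array([1, 0])
        lam = 0.05
        grad = sparse_loss_grad(ev, labels, lam)
        eps = 1e-6
        for idx in [(0, 0, 0, 0), (1, 1, 1, 1), (0, 1, 0, 1)]:
            up, down = ev.copy(), ev.copy()
            up[idx] += eps
            down[idx] -= eps
            num = (sparse_loss(up, labels, lam)[0] - sparse_loss(down, labels, lam)[0]) / (2 * eps)
            assert np.isclose(grad[idx], num, atol=1e-4)


class TestSplitBySubject:
    def _records(self, n_subjects, images_per_subject=2):
        rows = [
            {"subject_id": f"s{i:04d}", "image_id": f"s{i:04d}_{j}"}
            for i in range(n_subjects)
            for j in range(images_per_subject)
        ]
        return pd.DataFrame(rows)

    def test_subjects_never_split_across_folds(self):
        rec = self._records(3)
        fold = split_by_subject(rec, seed=0)
        per_subject = fold.groupby(rec["subject_id"]).nunique()
        assert (per_subject == 1).all()

    def test_thousand_subject_fractions(self):
        rec = self._records(1000)
        fold = split_by_subject(rec, seed=0)
        frac = (fold == "train").mean()
        assert abs(frac - 0.75) <= 0.02
        assert set(fold) == {"train", "val", "test"}
        assert len(fold) == len(rec)

    def test_order_invariance(self):
        rec = self._records(50)
        shuffled = rec.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = split_by_subject(rec, seed=4)
        b = split_by_subject(shuffled, seed=4)
        map_a = dict(zip(rec["subject_id"], a))
        map_b = dict(zip(shuffled["subject_id"], b))
        assert map_a == map_b

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_by_subject(self._records(10), fractions=(0.5, 0.2, 0.2), seed=0)


class TestSchedule:
    def test_endpoints(self):
        cfg = TrainConfig(epochs=100, initial_lr=1e-3, min_lr=1e-4)
        assert cosine_lr(0, cfg) == 1e-3
        assert cosine_lr(100, cfg) == 1e-4

    def test_monotone_nonincreasing(self):
        cfg = TrainConfig(epochs=40, initial_lr=0.05, min_lr=0.005)
        lrs = [cosine_lr(e, cfg) for e in range(41)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        assert min(lrs) == 0.005


class TestSelectLambda:
    def test_singleton(self):
        assert select_lambda({1e-5: 0.9}) == 1e-5

    def test_exhaustive_scan_example(self):
        cands = {0.0: 0.95, 1e-6: 0.95, 1e-5: 0.945, 1e-4: 0.80}
        assert select_lambda(cands, tolerance=0.01) == 1e-5
        # oracle: brute-force scan of the rule
        best = max(cands.values())
        ok = [l for l, a in cands.items() if a >= best - 0.01]
        assert select_lambda(cands) == max(ok)

    def test_all_within_tolerance_takes_largest(self):
        cands = {0.0: 0.95, 1e-3: 0.949, 1e-2: 0.948}
        assert select_lambda(cands, tolerance=0.01) == 1e-2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_lambda({})


def _toy_data(n=24, hw=40, seed=0):
    """Tiny linearly-separable image set: DR images carry a bright square."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 0.2, (n, 3, hw, hw)).astype(np.float32)
    y = (np.arange(n) % 2).astype(int)
    for i in range(n):
        if y[i] == 1:
            r, c = rng.integers(4, hw - 8, 2)
            X[i, :, r : r + 5, c : c + 5] += 2.0
    return X, y


class TestTrainLoop:
    def test_two_seeded_runs_bitwise_identical(self):
        X, y = _toy_data()
        cfg = TrainConfig(
            epochs=2, initial_lr=0.02, min_lr=0.002, batch_size=8, seed=3,
            augment=AugmentationConfig(flip=True, translate=True, noise=True),
        )
        m1, _ = train(build_reduced_backbone(seed=1), X, y, cfg)
        m2, _ = train(build_reduced_backbone(seed=1), X, y, cfg)
        for a, b in zip(m1.net.state(), m2.net.state()):
            assert (a == b).all()

    def test_loss_decreases_and_fits_toy_set(self):
        X, y = _toy_data(n=32)
        cfg = TrainConfig(
            epochs=8, initial_lr=0.05, min_lr=0.005, batch_size=8, seed=0,
            augment=AugmentationConfig(flip=True, translate=False, noise=False),
        )
        model, hist = train(build_reduced_backbone(seed=0), X, y, cfg)
        frame = hist.frame()
        assert len(frame) == 8
        assert frame.loss.iloc[-1] < frame.loss.iloc[0]
        from sparsebagnet.training import predict_scores

        acc = ((predict_scores(model, X) >= 0.5).astype(int) == y).mean()
        assert acc >= 0.9

    def test_empty_training_fold_rejected(self):
        cfg = TrainConfig(epochs=1)
        with pytest.raises(ValueError):
            train(build_reduced_backbone(seed=0), np.zeros((0, 3, 40, 40)), np.zeros(0), cfg)

    def test_history_tracks_schedule(self):
        X, y = _toy_data(n=8)
        cfg = TrainConfig(epochs=3, initial_lr=0.01, min_lr=0.001, batch_size=4, seed=0)
        _, hist = train(build_reduced_backbone(seed=0), X, y, cfg)
        frame = hist.frame()
        assert np.allclose(frame.lr, [cosine_lr(e, cfg) for e in range(3)])
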