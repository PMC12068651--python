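"""Sparse-objective training of the bag-of-local-features classifier.

The loss is cross-entropy on the mean-pooled logits plus an l1 penalty on
every evidence-map entry of every class,

    L = CE(softmax(mean_ij A), y) + lambda * sum_{i,j,c} |A_cij|,

batch-averaged in both terms so lambda is batch-size independent.  The
penalty drives the evidence maps toward sparse, strictly-local disease
evidence, which is what makes the extracted bounding boxes meaningful.

Also here: subject-grouped train/val/test splitting (75/10/15 by image
count, all images of a subject in one fold), the SGD loop with a clipped
cosine learning-rate schedule, training-fold-only augmentation, and the
validation-accuracy rule for choosing lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .model import SparseBagNet, softmax


class SplitError(ValueError):
    pass


@dataclass
class AugmentationConfig:
    flip: bool = True
    translate: bool = True
    rotate: bool = False
    color_jitter: bool = False
    random_crop: bool = False
    noise: bool = True
    max_translate_frac: float = 0.05
    max_rotate_deg: float = 15.0
    jitter: float = 0.1
    crop_scale: tuple[float, float] = (0.9, 1.0)
    noise_std: float = 0.1  # fresh gaussian noise per presentation, normalized scale


@dataclass
class TrainConfig:
    lambda_sparsity: float = 0.0
    epochs: int = 100
    initial_lr: float = 1e-3
    min_lr: float = 1e-4
    momentum: float = 0.9
    batch_size: int = 16
    seed: int = 0
    augment: AugmentationConfig = field(default_factory=AugmentationConfig)

    def validate(self):
        if self.lambda_sparsity < 0:
            raise ValueError("lambda_sparsity must be >= 0")
        if self.min_lr > self.initial_lr:
            raise ValueError("min_lr must not exceed initial_lr")


@dataclass
class TrainingHistory:
    epochs: list = field(default_factory=list)

    def append(self, **row):
        self.epochs.append(row)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)


def sparse_loss(
    evidence: np.ndarray, labels: np.ndarray, lambda_sparsity: float
) -> tuple[float, float, float]:
    """(total, ce_term, l1_term) of the sparse objective.

    `evidence`: (N, n_classes, h, w) evidence maps; logits are their
    spatial means.  Both terms are means over the batch; the l1 term sums
    |A| over all positions and both class maps of each image.
    """
    if lambda_sparsity < 0:
        raise ValueError("lambda_sparsity must be >= 0")
    evidence = np.asarray(evidence, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    logits = evidence.mean(axis=(2, 3))  # (N, C)
    probs = softmax(logits)
    n = len(labels)
    ce = float(-np.log(np.maximum(probs[np.arange(n), labels], 1e-300)).mean())
    l1 = float(np.abs(evidence).sum(axis=(1, 2, 3)).mean())
    return ce + lambda_sparsity * l1, ce, l1


def sparse_loss_grad(
    evidence: np.ndarray, labels: np.ndarray, lambda_sparsity: float
) -> np.ndarray:
    """d(total)/d(evidence), matching `sparse_loss`'s batch-mean reduction."""
    evidence = np.asarray(evidence, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    n, c, h, w = evidence.shape
    probs = softmax(evidence.mean(axis=(2, 3)))
    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0
    dce = (probs - onehot)[:, :, None, None] / (h * w)
    dl1 = lambda_sparsity * np.sign(evidence)
    return ((dce + dl1) / n).astype(np.float32)


def cosine_lr(epoch: int, config: TrainConfig) -> float:
    """Clipped cosine: anneal from initial_lr toward 0, floored at min_lr."""
    raw = config.initial_lr * 0.5 * (1.0 + np.cos(np.pi * epoch / config.epochs))
    return float(max(config.min_lr, raw))


def split_by_subject(
    records: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.75, 0.10, 0.15),
    seed: int = 0,
) -> pd.Series:
    """Assign each image to train/val/test keeping subjects whole.

    Subjects are shuffled (after canonical sorting, so the split depends
    only on the subject set, not record order) and filled into folds in
    order until each fold's image-count target is met.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise SplitError("fractions must sum to 1")
    if "subject_id" not in records:
        raise SplitError("records need a subject_id column")
    counts = records.groupby("subject_id").size()
    subjects = np.array(sorted(counts.index))
    if len(subjects) < 3:
        raise SplitError("need at least as many subjects as folds")
    rng = np.random.default_rng(seed)
    rng.shuffle(subjects)
    total = counts.sum()
    cum_targets = np.cumsum(fractions) * total
    fold_of = {}
    seen = 0
    fold_idx = 0
    names = ("train", "val", "test")
    for subj in subjects:
        while fold_idx < 2 and seen >= cum_targets[fold_idx]:
            fold_idx += 1
        fold_of[subj] = names[fold_idx]
        seen += counts[subj]
    return records["subject_id"].map(fold_of).rename("fold")


def _augment_batch(
    batch: np.ndarray, aug: AugmentationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Training-fold-only augmentation on an (N, 3, H, W) batch."""
    out = batch.copy()
    n, _, h, w = out.shape
    if aug.noise:
        out += rng.normal(0.0, aug.noise_std, out.shape).astype(np.float32)
    for i in range(n):
        if aug.flip and rng.uniform() < 0.5:
            out[i] = out[i, :, :, ::-1]
        if aug.flip and rng.uniform() < 0.5:
            out[i] = out[i, :, ::-1, :]
        if aug.translate:
            max_dy = int(aug.max_translate_frac * h)
            dy, dx = rng.integers(-max_dy, max_dy + 1, size=2)
            out[i] = np.roll(out[i], (dy, dx), axis=(1, 2))
            if dy > 0:
                out[i, :, :dy, :] = 0
            elif dy < 0:
                out[i, :, dy:, :] = 0
            if dx > 0:
                out[i, :, :, :dx] = 0
            elif dx < 0:
                out[i, :, :, dx:] = 0
        if aug.rotate:
            from scipy.ndimage import rotate as nd_rotate

            ang = rng.uniform(-aug.max_rotate_deg, aug.max_rotate_deg)
            out[i] = nd_rotate(out[i], ang, axes=(1, 2), reshape=False, order=1)
        if aug.color_jitter:
            gain = 1.0 + rng.uniform(-aug.jitter, aug.jitter, size=(3, 1, 1))
            offset = rng.uniform(-aug.jitter / 2, aug.jitter / 2, size=(3, 1, 1))
            out[i] = out[i] * gain + offset
        if aug.random_crop:
            from skimage.transform import resize

            scale = rng.uniform(*aug.crop_scale)
            ch, cw = int(h * scale), int(w * scale)
            top = rng.integers(0, h - ch + 1)
            left = rng.integers(0, w - cw + 1)
            crop = out[i, :, top : top + ch, left : left + cw]
            out[i] = resize(
                crop.transpose(1, 2, 0), (h, w), order=1, anti_aliasing=False,
                preserve_range=True,
            ).transpose(2, 0, 1)
    return out


def _predict_scores(model: SparseBagNet, images: np.ndarray, batch: int = 32) -> np.ndarray:
    """DR-class probability per image; images are (N, 3, H, W)."""
    scores = []
    for start in range(0, len(images), batch):
        ev = model.evidence_tensor(images[start : start + batch])
        logits = ev.mean(axis=(2, 3))
        scores.append(softmax(logits)[:, 1])
    return np.concatenate(scores)


def mean_abs_evidence(model: SparseBagNet, images: np.ndarray, batch: int = 32) -> float:
    """Mean |A| over all map cells and both classes — the sparsity readout."""
    tot, cnt = 0.0, 0
    for start in range(0, len(images), batch):
        ev = model.evidence_tensor(images[start : start + batch])
        tot += float(np.abs(ev).sum())
        cnt += ev.size
    return tot / cnt


def train(
    model: SparseBagNet,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    config: TrainConfig,
    val_images: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
) -> tuple[SparseBagNet, TrainingHistory]:
    """SGD with the clipped cosine schedule; keeps the best-validation weights.

    Images are (N, 3, H, W) float32, already preprocessed/normalized.
    Augmentation is applied to training batches only.  Fully seeded: two
    runs with identical inputs and config produce identical weights.
    """
    config.validate()
    if len(train_images) == 0:
        raise ValueError("empty training fold")
    rng = np.random.default_rng(config.seed)
    opt = nn.SGD(model.net.params(), lr=config.initial_lr, momentum=config.momentum)
    history = TrainingHistory()
    best_state, best_acc = None, -1.0
    n = len(train_images)
    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config)
        opt.lr = lr
        order = rng.permutation(n)
        tot_sum = ce_sum = l1_sum = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = train_images[idx]
            batch = _augment_batch(batch, config.augment, rng)
            labels = train_labels[idx]
            ev = model.evidence_tensor(batch, train=True)
            total, ce, l1 = sparse_loss(ev, labels, config.lambda_sparsity)
            dmaps = sparse_loss_grad(ev, labels, config.lambda_sparsity)
            model.net.backward(dmaps)
            opt.step()
            tot_sum += total * len(idx)
            ce_sum += ce * len(idx)
            l1_sum += l1 * len(idx)
        row = {
            "epoch": epoch,
            "lr": lr,
            "loss": tot_sum / n,
            "ce": ce_sum / n,
            "l1": l1_sum / n,
        }
        if val_images is not None and len(val_images):
            scores = _predict_scores(model, val_images)
            acc = float(((scores >= 0.5).astype(int) == val_labels).mean())
            row["val_accuracy"] = acc
            if acc >= best_acc:
                best_acc = acc
                best_state = model.net.state()
        history.append(**row)
    if best_state is not None:
        model.net.load_state(best_state)
    return model, history


def select_lambda(
    candidates: dict[float, float], tolerance: float = 0.01
) -> float:
    """Largest lambda whose validation accuracy is within `tolerance` of the
    best — the sparsest model at (essentially) no accuracy cost."""
    if not candidates:
        raise ValueError("no lambda candidates")
    best = max(candidates.values())
    eligible = [lam for lam, acc in candidates.items() if acc >= best - tolerance]
    return max(eligible)


def predict_scores(model: SparseBagNet, images: np.ndarray, batch: int = 32) -> np.ndarray:
    return _predict_scores(model, images, batch)
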