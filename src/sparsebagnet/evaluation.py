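"""Quantitative evaluation of the screening model and its explanations.

Classification: accuracy, AUC, sensitivity, specificity, precision with
percentile bootstrap confidence intervals (1000 unstratified resamples by
default).  Localization: the fraction of explanation boxes that contain at
least one annotated lesion pixel ("localization precision"), a random-box
chance baseline that avoids the black background, grader-consensus masks
(pixelwise union / intersection), and patch-level dice between two
annotations rasterized onto the model's patch lattice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .explanation import ExplanationSet
from .preprocess import FOREGROUND_THRESHOLD


class AlignmentError(ValueError):
    pass


class SamplingExhaustionError(RuntimeError):
    pass


@dataclass
class MetricWithCI:
    point: float
    ci_low: float
    ci_high: float


@dataclass
class MetricsReport:
    accuracy: MetricWithCI
    auc: MetricWithCI | None
    sensitivity: MetricWithCI
    specificity: MetricWithCI
    precision: MetricWithCI
    n_bootstrap: int = 1000
    ci_level: float = 0.95

    def to_dict(self) -> dict:
        def clean(x):
            return None if x is None or np.isnan(x) else float(x)

        out = {"n_bootstrap": self.n_bootstrap, "ci_level": self.ci_level}
        for name in ("accuracy", "auc", "sensitivity", "specificity", "precision"):
            m = getattr(self, name)
            out[name] = None if m is None else [clean(m.point), clean(m.ci_low), clean(m.ci_high)]
        return out


def _confusion_metrics(labels: np.ndarray, preds: np.ndarray) -> dict[str, float]:
    tp = int(((preds == 1) & (labels == 1)).sum())
    tn = int(((preds == 0) & (labels == 0)).sum())
    fp = int(((preds == 1) & (labels == 0)).sum())
    fn = int(((preds == 0) & (labels == 1)).sum())
    div = lambda a, b: a / b if b else np.nan
    return {
        "accuracy": div(tp + tn, tp + tn + fp + fn),
        "sensitivity": div(tp, tp + fn),
        "specificity": div(tn, tn + fp),
        "precision": div(tp, tp + fp),
    }


def classification_metrics(
    labels, scores, threshold: float = 0.5, n_bootstrap: int = 1000, seed: int = 0
) -> MetricsReport:
    """Point estimates plus percentile bootstrap CIs (2.5/97.5 percentiles,
    unstratified resampling with replacement, seeded)."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must align")
    preds = (scores >= threshold).astype(int)
    point = _confusion_metrics(labels, preds)
    both_classes = len(np.unique(labels)) == 2
    point["auc"] = float(roc_auc_score(labels, scores)) if both_classes else None
    rng = np.random.default_rng(seed)
    n = len(labels)
    samples: dict[str, list] = {k: [] for k in ("accuracy", "auc", "sensitivity", "specificity", "precision")}
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        lb, sc = labels[idx], scores[idx]
        pr = (sc >= threshold).astype(int)
        for k, v in _confusion_metrics(lb, pr).items():
            samples[k].append(v)
        if len(np.unique(lb)) == 2:
            samples["auc"].append(float(roc_auc_score(lb, sc)))

    def ci(name, pt):
        if pt is None:
            return None
        vals = np.asarray([v for v in samples[name] if not np.isnan(v)])
        if len(vals) == 0:
            return MetricWithCI(pt, pt, pt)
        lo, hi = np.percentile(vals, [2.5, 97.5])
        return MetricWithCI(float(pt), float(lo), float(hi))

    return MetricsReport(
        accuracy=ci("accuracy", point["accuracy"]),
        auc=ci("auc", point["auc"]),
        sensitivity=ci("sensitivity", point["sensitivity"]),
        specificity=ci("specificity", point["specificity"]),
        precision=ci("precision", point["precision"]),
        n_bootstrap=n_bootstrap,
    )


def localization_precision(
    explanations: list[ExplanationSet], masks: list[np.ndarray]
) -> tuple[float, pd.DataFrame]:
    """Fraction of boxes containing >= 1 annotated lesion pixel.

    Pooled over all boxes of all images (images without boxes do not enter
    the denominator); a per-image breakdown is returned alongside.
    """
    if len(explanations) != len(masks):
        raise AlignmentError("one mask per explanation required")
    rows = []
    hits = total = 0
    for expl, mask in zip(explanations, masks):
        if expl.overlay is not None and expl.overlay.shape != mask.shape:
            raise AlignmentError(f"mask size {mask.shape} mismatches image {expl.overlay.shape}")
        img_hits = sum(1 for b in expl.boxes if b.contains_any(mask))
        n_boxes = len(expl.boxes)
        hits += img_hits
        total += n_boxes
        rows.append(
            {
                "image_id": expl.image_id,
                "n_boxes": n_boxes,
                "n_hits": img_hits,
                "precision": img_hits / n_boxes if n_boxes else np.nan,
            }
        )
    pooled = hits / total if total else np.nan
    return pooled, pd.DataFrame(rows)


def random_box_baseline(
    image: np.ndarray,
    mask: np.ndarray,
    n_boxes: int = 20,
    box_side: int = 33,
    black_fraction_limit: float = 0.10,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> float:
    """Chance-level localization: hit fraction of random boxes.

    Boxes are sampled uniformly over valid positions and rejected when more
    than `black_fraction_limit` of their pixels are black (all channels
    below 10/255), so chance is measured over the retinal field rather than
    the background.
    """
    if image.shape[:2] != mask.shape:
        raise AlignmentError("image and mask must align")
    h, w = mask.shape
    if h < box_side or w < box_side:
        raise ValueError("image smaller than the box side")
    black = (image < FOREGROUND_THRESHOLD).all(axis=2)
    rng = np.random.default_rng(seed)
    hits = accepted = attempts = 0
    while accepted < n_boxes:
        if attempts >= max_attempts:
            raise SamplingExhaustionError(
                f"could not place {n_boxes} boxes in {max_attempts} attempts"
            )
        attempts += 1
        r = int(rng.integers(0, h - box_side + 1))
        c = int(rng.integers(0, w - box_side + 1))
        patch_black = black[r : r + box_side, c : c + box_side].mean()
        if patch_black > black_fraction_limit:
            continue
        accepted += 1
        if mask[r : r + box_side, c : c + box_side].any():
            hits += 1
    return hits / n_boxes


def consensus_masks(per_grader: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """(union, intersection) of >= 2 graders' binary masks."""
    if len(per_grader) < 2:
        raise ValueError("need at least two graders")
    shapes = {m.shape for m in per_grader}
    if len(shapes) != 1:
        raise AlignmentError(f"mask sizes differ: {shapes}")
    stack = np.stack([m.astype(bool) for m in per_grader])
    return stack.any(axis=0), stack.all(axis=0)


def _positive_patches(mask: np.ndarray, patch: int, stride: int) -> np.ndarray:
    """Boolean lattice: patch positive iff it contains >= 1 annotated pixel."""
    win = np.lib.stride_tricks.sliding_window_view(mask, (patch, patch))
    return win[::stride, ::stride].any(axis=(2, 3))


def patch_dice(
    mask_a: np.ndarray, mask_b: np.ndarray, patch: int = 33, stride: int = 8
) -> float:
    """Dice overlap of two annotations on the patch lattice.

    Both masks are rasterized to the valid-placement lattice (patch
    positive iff it contains any annotated pixel); dice is computed over
    the positive-patch sets and defined as 1.0 when both are empty.
    """
    if stride <= 0:
        raise ValueError("stride must be positive")
    if mask_a.shape != mask_b.shape:
        raise AlignmentError("masks must align")
    pa = _positive_patches(mask_a.astype(bool), patch, stride)
    pb = _positive_patches(mask_b.astype(bool), patch, stride)
    na, nb = int(pa.sum()), int(pb.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((pa & pb).sum()) / (na + nb)
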