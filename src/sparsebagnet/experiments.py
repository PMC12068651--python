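"""Desk-scale benchmark study on the synthetic screening task.

One place defines the reduced study conditions — cohort size, prevalence,
backbone width, sparsity grid, schedule — so the test suite, the example
scripts and the acceptance script all run the *same* experiment instead of
three slightly different ones.

The study mirrors the full-scale development pipeline end to end at CPU
scale: generate a two-eyes-per-subject cohort (128 px scenes, 30% DR
prevalence), split it subject-wise 75/10/15, normalize by training-fold
statistics, train the reduced sparse bag-of-local-features model with the
clipped-cosine SGD schedule, and evaluate screening metrics plus
bounding-box lesion localization on held-out scenes.  Localization is
scored on an annotated pool whose grade composition (13 mild : 32
moderate) matches the roughly 20:45 ratio of the annotated evaluation
subset used at full scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import localization_precision
from .explanation import extract_boxes
from .model import CLASS_DR, SparseBagNet, build_reduced_backbone
from .preprocess import NormalizationStats, apply_normalization, fit_normalization
from .synthetic import (
    GeneratorConfig,
    ReaderStudySet,
    StratumShortageError,
    generate_dataset,
    generate_scene,
    sample_reader_study,
    scenes_metadata,
)
from .training import (
    AugmentationConfig,
    TrainConfig,
    TrainingHistory,
    mean_abs_evidence,
    predict_scores,
    split_by_subject,
    train,
)


@dataclass(frozen=True)
class ReducedStudyConfig:
    """Study conditions of the reduced synthetic benchmark."""

    n_subjects: int = 200
    prevalence: float = 0.30
    width: int = 2
    epochs: int = 35
    initial_lr: float = 0.05
    min_lr: float = 0.002
    batch_size: int = 16
    lambda_sparsity: float = 1e-3
    #: sparsity-response grid: quick trainings at increasing penalty
    lambda_grid: tuple[float, ...] = (0.0, 1e-4, 1e-3)
    grid_subjects: int = 100  # 200 images
    grid_epochs: int = 12
    grid_width: int = 1  # sparsity-response runs use the narrow backbone
    #: annotated localization pool (grade -> image count), ~20:45 mild:moderate
    loc_pool: tuple[tuple[int, int], ...] = ((1, 13), (2, 32))
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)


@dataclass
class Cohort:
    scenes: list
    images: np.ndarray  # (N, 3, H, W) normalized
    labels: np.ndarray
    folds: np.ndarray  # "train" | "val" | "test" per image
    stats: NormalizationStats


@dataclass
class StudyResult:
    model: SparseBagNet
    history: TrainingHistory
    cohort: Cohort
    auc: float
    accuracy: float
    loc_precision: float
    n_boxes: int
    mean_abs_evidence: float


def _augmentations() -> AugmentationConfig:
    return AugmentationConfig(flip=True, translate=True, noise=True)


def make_cohort(config: ReducedStudyConfig, seed: int, n_subjects: int | None = None) -> Cohort:
    scenes = generate_dataset(
        n_subjects or config.n_subjects, config.prevalence, config.generator, seed
    )
    folds = split_by_subject(scenes_metadata(scenes), seed=seed).to_numpy()
    stats = fit_normalization(
        [s.image for s, f in zip(scenes, folds) if f == "train"]
    )
    images = np.stack(
        [apply_normalization(s.image, stats).transpose(2, 0, 1) for s in scenes]
    ).astype(np.float32)
    labels = np.array([s.label for s in scenes])
    return Cohort(scenes=scenes, images=images, labels=labels, folds=folds, stats=stats)


def train_candidate(
    cohort: Cohort,
    config: ReducedStudyConfig,
    lambda_sparsity: float,
    seed: int,
    epochs: int | None = None,
    width: int | None = None,
) -> tuple[SparseBagNet, TrainingHistory]:
    tr = cohort.folds == "train"
    va = cohort.folds == "val"
    model = build_reduced_backbone(seed=seed, width=width or config.width)
    model.normalization = cohort.stats
    cfg = TrainConfig(
        lambda_sparsity=lambda_sparsity,
        epochs=epochs or config.epochs,
        initial_lr=config.initial_lr,
        min_lr=config.min_lr,
        batch_size=config.batch_size,
        seed=seed,
        augment=_augmentations(),
    )
    return train(
        model, cohort.images[tr], cohort.labels[tr], cfg,
        cohort.images[va], cohort.labels[va],
    )


def localization_pool(config: ReducedStudyConfig, seed: int) -> list:
    """Annotated DR scenes, disjoint from any cohort, for box scoring."""
    pool = []
    k = 0
    for grade, count in config.loc_pool:
        for _ in range(count):
            pool.append(
                generate_scene(config.generator, seed=90_000 + seed * 997 + k, grade=grade)
            )
            k += 1
    return pool


def score_localization(
    model: SparseBagNet, pool: list, stats: NormalizationStats
) -> tuple[float, int]:
    expls, masks = [], []
    for k, scene in enumerate(pool):
        emap, _ = model.forward(apply_normalization(scene.image, stats))
        expls.append(extract_boxes(emap, CLASS_DR, image_id=str(k)))
        masks.append(scene.mask)
    pooled, _ = localization_precision(expls, masks)
    return pooled, sum(len(e.boxes) for e in expls)


def run_recovery_study(
    config: ReducedStudyConfig | None = None, seed: int = 0
) -> StudyResult:
    """Full reduced pipeline: train the sparse model, score held-out
    screening performance and bounding-box lesion localization."""
    from sklearn.metrics import roc_auc_score

    config = config or ReducedStudyConfig()
    cohort = make_cohort(config, seed)
    model, history = train_candidate(cohort, config, config.lambda_sparsity, seed)
    te = cohort.folds == "test"
    scores = predict_scores(model, cohort.images[te])
    auc = float(roc_auc_score(cohort.labels[te], scores))
    accuracy = float(((scores >= 0.5).astype(int) == cohort.labels[te]).mean())
    loc, n_boxes = score_localization(model, localization_pool(config, seed), cohort.stats)
    return StudyResult(
        model=model,
        history=history,
        cohort=cohort,
        auc=auc,
        accuracy=accuracy,
        loc_precision=loc,
        n_boxes=n_boxes,
        mean_abs_evidence=mean_abs_evidence(model, cohort.images[te]),
    )


def run_sparsity_grid(
    config: ReducedStudyConfig | None = None, seed: int = 0
) -> dict[float, dict[str, float]]:
    """Quick trainings over the sparsity grid on a 200-image cohort;
    reports held-out mean |A| and validation accuracy per penalty."""
    config = config or ReducedStudyConfig()
    cohort = make_cohort(config, seed, n_subjects=config.grid_subjects)
    te = cohort.folds == "test"
    out: dict[float, dict[str, float]] = {}
    for lam in config.lambda_grid:
        model, history = train_candidate(
            cohort, config, lam, seed, epochs=config.grid_epochs, width=config.grid_width
        )
        frame = history.frame()
        out[lam] = {
            "mean_abs_evidence": mean_abs_evidence(model, cohort.images[te]),
            "val_accuracy": float(frame.val_accuracy.max()),
        }
    return out


def _feasible_threshold(
    scores: np.ndarray, grades: np.ndarray, n_correct: int = 15, n_wrong: int = 5
) -> float | None:
    """Operating point at which every reader-study stratum is feasible.

    Needs >= n_wrong false positives and >= n_correct true negatives on
    grade 0, and >= n_correct true positives plus >= n_wrong false
    negatives on each DR grade.  Among feasible thresholds, the one
    closest to 0.5 is returned; None if no threshold works.
    """
    cuts = np.unique(scores)
    candidates = np.concatenate([[0.0], (cuts[:-1] + cuts[1:]) / 2, [1.0], [0.5]])
    feasible = []
    for t in candidates:
        ok = True
        for grade in (0, 1, 2):
            s = scores[grades == grade]
            n_pos = int((s >= t).sum())
            n_neg = len(s) - n_pos
            if grade == 0:
                ok &= n_pos >= n_wrong and n_neg >= n_correct
            else:
                ok &= n_pos >= n_correct and n_neg >= n_wrong
            if not ok:
                break
        if ok:
            feasible.append(float(t))
    if not feasible:
        return None
    return min(feasible, key=lambda t: (abs(t - 0.5), t))


def build_reader_study(
    model: SparseBagNet,
    config: ReducedStudyConfig,
    seed: int,
    per_grade_pool: int = 120,
) -> ReaderStudySet:
    """Construct the 60-image by-design study set from model predictions.

    The constructor needs at least 15 correctly and 5 incorrectly
    classified candidates per grade 0/1/2.  Predictions are the trained
    model's scores thresholded at 0.5 on a fresh pool; if some stratum
    lacks candidates at that operating point (at reduced scale the model
    can be error-free on a grade), the pool is enlarged and, if needed,
    the operating point is recalibrated to the feasible threshold closest
    to 0.5 — the full-scale study draws its strata from a test pool large
    enough that the default operating point supplies every stratum.
    """
    stats = model.normalization

    def pool_and_scores(n_per_grade):
        scenes = []
        for grade in (0, 1, 2):
            for k in range(n_per_grade):
                scenes.append(
                    generate_scene(
                        config.generator,
                        seed=70_000 + seed * 991 + grade * 10_000 + k,
                        grade=grade,
                    )
                )
        imgs = np.stack(
            [apply_normalization(s.image, stats).transpose(2, 0, 1) for s in scenes]
        ).astype(np.float32)
        return scenes, predict_scores(model, imgs)

    last_error: StratumShortageError | None = None
    for n_per_grade in (per_grade_pool, 3 * per_grade_pool):
        scenes, scores = pool_and_scores(n_per_grade)
        grades = np.array([s.grade for s in scenes])
        for threshold in (0.5, _feasible_threshold(scores, grades)):
            if threshold is None:
                continue
            preds = (scores >= threshold).astype(int)
            try:
                return sample_reader_study(scenes, preds, seed=seed)
            except StratumShortageError as err:
                last_error = err
    raise last_error
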