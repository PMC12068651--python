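"""Synthetic fundus-like scenes with planted, mask-annotated lesions.

Emulates the structure of a diabetic-retinopathy screening dataset: a
bright roughly circular retinal field on black background, two eyes per
subject, and small focal lesions — microaneurysm- (MA), hemorrhage- (HE),
exudate- (EX) and soft-exudate-like (SE) spots — whose presence defines
the image-level DR grade and whose exact rendered footprints define the
pixel-level localization ground truth.

Healthy (grade 0) scenes may carry non-lesion distractor artifacts
(dust/drusen-like faint gray spots, excluded from the lesion mask), and
lesion contrast is drawn with a low tail, so the screening task is not
trivially separable and a trained screening model makes errors in every
grade stratum — as real models do.

Also provides the stratified reader-study sampler: 60 images, 20 per
grade 0/1/2, of which 15 were classified correctly by the model and 5
incorrectly, giving 75% model accuracy on the study set by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

LESION_TYPES = ("MA", "HE", "EX", "SE")

#: base retinal-field colour (RGB, unit scale) before shading
_FUNDUS_RGB = np.array([0.78, 0.42, 0.20])
#: per-type colour direction of the intensity offset (signed, unit scale)
_LESION_RGB = {
    "MA": np.array([-0.55, -0.9, -0.6]),  # small dark-red dot
    "HE": np.array([-0.65, -0.95, -0.7]),  # dark blot
    "EX": np.array([0.5, 0.95, 0.35]),  # bright yellowish deposit
    "SE": np.array([0.45, 0.75, 0.55]),  # fluffy pale patch
}
class ConfigurationError(ValueError):
    pass


class StratumShortageError(RuntimeError):
    """A reader-study stratum lacks candidates; names the stratum."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic screening task.

    Sizes are pixels on the output grid; contrasts are signed intensity
    offsets on the unit intensity scale.  Defaults target 128x128 scenes,
    keeping lesion scale relative to the model's 33-px patches comparable
    to real 512-px fundus photographs.
    """

    image_size: int = 128
    disc_radius_frac: tuple[float, float] = (0.42, 0.48)
    #: grade -> (min, max) planted lesion count (inclusive)
    lesions_per_grade: dict = field(
        default_factory=lambda: {0: (0, 0), 1: (1, 3), 2: (4, 10)}
    )
    ma_radius: tuple[int, int] = (2, 4)
    he_radius: tuple[int, int] = (5, 12)
    ex_radius: tuple[int, int] = (4, 10)
    #: |contrast| range; a fraction of DR scenes are "subtle presentations"
    #: whose lesions all draw from the low-contrast range
    contrast: tuple[float, float] = (0.10, 0.35)
    low_contrast_prob: float = 0.25
    low_contrast: tuple[float, float] = (0.04, 0.10)
    artifact_prob: float = 0.5  # P(grade-0 scene carries subtle distractor specks)
    artifact_count: tuple[int, int] = (1, 3)
    #: P(grade-0 scene carries 1-2 full-contrast MA-like spots): reference
    #: labels in screening data are imperfect, and such images drive the
    #: model's (rare) false positives
    confounder_prob: float = 0.06
    vessels: int = 4
    noise_scale: float = 0.02

    def validate(self) -> None:
        if self.image_size < 64:
            raise ConfigurationError("image_size must be >= 64")
        rmax = max(self.ma_radius[1], self.he_radius[1], self.ex_radius[1])
        if rmax >= self.disc_radius_frac[0] * self.image_size:
            raise ConfigurationError("lesion radius exceeds disc radius")
        for g, (lo, hi) in self.lesions_per_grade.items():
            if lo > hi or lo < 0:
                raise ConfigurationError(f"bad lesion-count range for grade {g}")


@dataclass(frozen=True)
class SyntheticLesion:
    lesion_type: str  # MA | HE | EX | SE
    center: tuple[int, int]  # (row, col)
    radius: int
    contrast: float  # signed unit-scale intensity offset


@dataclass
class SyntheticScene:
    image: np.ndarray  # (H, W, 3) float32 in [0, 1]
    mask: np.ndarray  # (H, W) bool, union of lesion footprints
    lesions: list
    grade: int
    subject_id: str
    eye: str
    seed: int

    @property
    def label(self) -> int:
        return int(self.grade >= 1)


@dataclass
class ReaderStudySet:
    """The by-design 60-image study set (20 per grade, 15 correct + 5 not)."""

    records: pd.DataFrame  # columns: index, grade, label, prediction, model_correct

    @property
    def model_accuracy(self) -> float:
        return float(self.records["model_correct"].mean())

    @property
    def dr_fraction(self) -> float:
        return float((self.records["grade"] >= 1).mean())


def _lesion_shape_rng(lesion: SyntheticLesion) -> np.random.Generator:
    # blob shape must be a pure function of the lesion's own fields so a
    # lesion can be re-rendered independently of the scene that made it
    entropy = (
        LESION_TYPES.index(lesion.lesion_type),
        lesion.center[0],
        lesion.center[1],
        lesion.radius,
        int(abs(lesion.contrast) * 1e6),
    )
    return np.random.default_rng(np.random.SeedSequence(entropy))


def render_lesion_footprint(lesion: SyntheticLesion, shape: tuple[int, int]) -> np.ndarray:
    """Boolean footprint of one lesion on an (H, W) grid.

    MA/EX/SE are discs; HE is an irregular blob (union of jittered discs).
    Deterministic given the lesion fields alone.
    """
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    cy, cx = lesion.center
    if lesion.lesion_type == "HE":
        rng = _lesion_shape_rng(lesion)
        foot = np.zeros(shape, bool)
        n_sub = rng.integers(3, 6)
        for _ in range(n_sub):
            dy, dx = rng.integers(-lesion.radius // 2, lesion.radius // 2 + 1, 2)
            r = max(2, int(lesion.radius * rng.uniform(0.4, 0.8)))
            foot |= (rr - (cy + dy)) ** 2 + (cc - (cx + dx)) ** 2 <= r**2
        return foot
    return (rr - cy) ** 2 + (cc - cx) ** 2 <= lesion.radius**2


def _paint(image: np.ndarray, foot: np.ndarray, contrast: float, rgb: np.ndarray) -> None:
    image[foot] = np.clip(image[foot] + contrast * rgb, 0.0, 1.0)


def _background(cfg: GeneratorConfig, rng: np.random.Generator):
    """Retinal disc with radial falloff, low-frequency shading and vessels."""
    from scipy.ndimage import gaussian_filter

    n = cfg.image_size
    radius = rng.uniform(*cfg.disc_radius_frac) * n
    cy = n / 2 + rng.uniform(-2, 2)
    cx = n / 2 + rng.uniform(-2, 2)
    rr, cc = np.mgrid[0:n, 0:n]
    dist = np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2)
    disc = dist <= radius
    shade = 1.0 - 0.35 * (dist / radius) ** 2
    lowfreq = gaussian_filter(rng.normal(0.0, 1.0, (n, n)), sigma=n / 8)
    lowfreq = 0.08 * lowfreq / (np.abs(lowfreq).max() + 1e-9)
    base = (shade + lowfreq)[..., None] * _FUNDUS_RGB[None, None, :]
    image = np.where(disc[..., None], base, 0.0)
    # dark vessel-like curves: quadratic arcs from near-centre outward
    for _ in range(cfg.vessels):
        t = np.linspace(0, 1, 4 * n)
        theta = rng.uniform(0, 2 * np.pi)
        curv = rng.uniform(-2.0, 2.0)
        r_t = t * radius * 0.95
        ang = theta + curv * t
        vy = np.clip(cy + r_t * np.sin(ang), 0, n - 1).astype(int)
        vx = np.clip(cx + r_t * np.cos(ang), 0, n - 1).astype(int)
        width = rng.integers(1, 3)
        for dy in range(-width // 2, width // 2 + 1):
            yy = np.clip(vy + dy, 0, n - 1)
            image[yy, vx] *= 0.55
    image += rng.normal(0.0, cfg.noise_scale, image.shape)
    image = np.clip(image, 0.0, 1.0)
    image[~disc] = 0.0
    return image.astype(np.float32), disc, (cy, cx, radius)


def _sample_lesion(
    cfg: GeneratorConfig, rng: np.random.Generator, disc_geom, subtle: bool = False
) -> SyntheticLesion:
    cy, cx, radius = disc_geom
    ltype = rng.choice(LESION_TYPES, p=[0.35, 0.25, 0.3, 0.1])
    rlo, rhi = {
        "MA": cfg.ma_radius,
        "HE": cfg.he_radius,
        "EX": cfg.ex_radius,
        "SE": cfg.ex_radius,
    }[ltype]
    lr = int(rng.integers(rlo, rhi + 1))
    # rejection-free placement: uniform angle, radius bounded to keep the
    # whole footprint inside the disc (HE blobs jitter beyond their radius)
    margin = 1.6 * lr if ltype == "HE" else lr
    rmax = max(1.0, radius - margin - 2)
    rho = np.sqrt(rng.uniform(0, 1)) * rmax
    ang = rng.uniform(0, 2 * np.pi)
    center = (int(round(cy + rho * np.sin(ang))), int(round(cx + rho * np.cos(ang))))
    mag = rng.uniform(*(cfg.low_contrast if subtle else cfg.contrast))
    # contrast direction (dark vs bright) lives in the per-type colour vector
    return SyntheticLesion(lesion_type=str(ltype), center=center, radius=lr, contrast=mag)


def generate_scene(
    config: GeneratorConfig,
    seed: int,
    grade: int = 0,
    subject_id: str = "s0",
    eye: str = "left",
) -> SyntheticScene:
    """One synthetic fundus scene; bit-deterministic in (config, seed, grade)."""
    config.validate()
    if grade not in config.lesions_per_grade:
        raise ConfigurationError(f"no lesion-count range for grade {grade}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, grade]))
    image, disc, geom = _background(config, rng)
    n = config.image_size
    mask = np.zeros((n, n), bool)
    lo, hi = config.lesions_per_grade[grade]
    n_lesions = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
    # subtle presentation: all of this scene's lesions are low-contrast
    subtle = bool(rng.uniform() < config.low_contrast_prob)
    lesions = []
    for _ in range(n_lesions):
        lesion = _sample_lesion(config, rng, geom, subtle=subtle)
        foot = render_lesion_footprint(lesion, (n, n))
        _paint(image, foot, lesion.contrast, _LESION_RGB[lesion.lesion_type])
        mask |= foot
        lesions.append(lesion)
    if grade == 0:
        u = rng.uniform()
        if u < config.confounder_prob:
            # confounder scene: full-contrast MA-like spots under a healthy
            # reference label — screening labels are imperfect, and images
            # like these drive the model's (rare) false positives
            for _ in range(int(rng.integers(2, 5))):
                spec = _sample_lesion(config, rng, geom, subtle=False)
                spec = replace(spec, lesion_type="MA", radius=min(spec.radius, 4))
                foot = render_lesion_footprint(spec, (n, n))
                _paint(image, foot, spec.contrast, _LESION_RGB["MA"])
        elif u < config.confounder_prob + config.artifact_prob:
            # distractor specks: MA-coloured at subtle contrast — pigment
            # spots and dust that mimic faint lesions
            n_art = int(rng.integers(config.artifact_count[0], config.artifact_count[1] + 1))
            for _ in range(n_art):
                spec = _sample_lesion(config, rng, geom, subtle=True)
                spec = replace(spec, lesion_type="MA", radius=min(spec.radius, 3))
                foot = render_lesion_footprint(spec, (n, n))
                _paint(image, foot, spec.contrast, _LESION_RGB["MA"])
    if (len(lesions) == 0) != (grade == 0):
        raise AssertionError("grade/lesion-count invariant violated")
    return SyntheticScene(
        image=image, mask=mask, lesions=lesions, grade=grade,
        subject_id=subject_id, eye=eye, seed=seed,
    )


def generate_dataset(
    n_subjects: int,
    prevalence: float = 0.27,
    config: GeneratorConfig | None = None,
    seed: int = 0,
    dr_grades: tuple[int, ...] = (1, 2),
) -> list[SyntheticScene]:
    """Two-eyes-per-subject cohort with subject-level DR status.

    DR status is drawn per subject (Bernoulli(prevalence), default the
    27% DR prevalence of large screening programmes); both eyes of a DR
    subject receive a DR grade drawn uniformly from `dr_grades`.
    """
    if not 0 <= prevalence <= 1:
        raise ConfigurationError("prevalence must lie in [0, 1]")
    if n_subjects < 1:
        raise ConfigurationError("need at least one subject")
    config = config or GeneratorConfig()
    config.validate()
    root = np.random.SeedSequence([seed, n_subjects])
    master = np.random.default_rng(root)
    scenes = []
    for si in range(n_subjects):
        diseased = master.uniform() < prevalence
        for ei, eye in enumerate(("left", "right")):
            grade = int(master.choice(dr_grades)) if diseased else 0
            scene_seed = int(master.integers(0, 2**31 - 1))
            scenes.append(
                generate_scene(config, scene_seed, grade=grade,
                               subject_id=f"subj{si:05d}", eye=eye)
            )
    return scenes


def scenes_metadata(scenes: list[SyntheticScene]) -> pd.DataFrame:
    rows = [
        {
            "image_id": f"{s.subject_id}_{s.eye}",
            "subject_id": s.subject_id,
            "eye": s.eye,
            "grade": s.grade,
            "label": s.label,
            "seed": s.seed,
        }
        for s in scenes
    ]
    return pd.DataFrame(rows)


def sample_reader_study(
    scenes: list[SyntheticScene],
    predictions: np.ndarray,
    seed: int = 0,
    per_grade: int = 20,
    n_correct: int = 15,
) -> ReaderStudySet:
    """Stratified study constructor: `per_grade` images per grade 0/1/2,
    `n_correct` classified correctly by the model and the rest incorrectly.

    With the defaults this fixes model accuracy on the study set at
    45/60 = 75% and the DR fraction at 40/60, both by design.  Sampling is
    without replacement and deterministic given the seed.
    """
    predictions = np.asarray(predictions, dtype=int)
    if len(predictions) != len(scenes):
        raise ValueError("one prediction per scene required")
    n_wrong = per_grade - n_correct
    rng = np.random.default_rng(np.random.SeedSequence([seed, per_grade, n_correct]))
    chosen = []
    for grade in (0, 1, 2):
        for want_correct, need in ((True, n_correct), (False, n_wrong)):
            pool = [
                i
                for i, s in enumerate(scenes)
                if s.grade == grade and (predictions[i] == s.label) == want_correct
            ]
            tag = "correctly" if want_correct else "incorrectly"
            if len(pool) < need:
                raise StratumShortageError(
                    f"grade {grade}, {tag} classified: need {need}, have {len(pool)}"
                )
            chosen.extend(
                (int(i), grade, bool(want_correct))
                for i in rng.choice(pool, size=need, replace=False)
            )
    records = pd.DataFrame(
        {
            "index": [c[0] for c in chosen],
            "grade": [c[1] for c in chosen],
            "label": [scenes[c[0]].label for c in chosen],
            "prediction": [int(predictions[c[0]]) for c in chosen],
            "model_correct": [c[2] for c in chosen],
        }
    )
    return ReaderStudySet(records=records)
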