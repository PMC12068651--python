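"""Fundus preprocessing: circle-fit square crop and training-set normalization.

A fundus photograph is a bright, roughly circular retinal field on a dark
background.  `crop_to_square` locates that field (threshold, largest
connected component, least-squares circle fit to its boundary), crops the
circle's bounding square and resamples to a fixed side (512 px by
default).  Intensities are then standardized per channel by statistics
fitted once on the training fold and reused verbatim everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology, transform

FOREGROUND_THRESHOLD = 10.0 / 255.0


@dataclass
class FundusImage:
    """A fundus photograph plus the metadata the pipeline keys on."""

    pixels: np.ndarray  # (H, W, 3), unit-scale intensities
    image_id: str = ""
    subject_id: str = ""
    grade: int = 0

    def __post_init__(self):
        h, w = self.pixels.shape[:2]
        if h < 64 or w < 64:
            raise ValueError("fundus images must be at least 64x64")
        if not 0 <= self.grade <= 4:
            raise ValueError("grade must be in 0..4")

    @property
    def label(self) -> int:
        return int(self.grade >= 1)


class CircleFitError(ValueError):
    """No usable bright circular field found."""


class ZeroStdError(ValueError):
    """A channel is constant on the training fold."""


@dataclass
class CircleFit:
    center: tuple[float, float]  # (row, col)
    radius: float


@dataclass
class NormalizationStats:
    """Per-channel pooled mean/std of the training fold."""

    mean: np.ndarray  # (3,)
    std: np.ndarray  # (3,)

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @staticmethod
    def from_dict(d: dict) -> "NormalizationStats":
        return NormalizationStats(np.asarray(d["mean"], float), np.asarray(d["std"], float))


def fit_circle_lsq(rows: np.ndarray, cols: np.ndarray) -> CircleFit:
    """Algebraic (Kåsa) least-squares circle through boundary points."""
    a = np.column_stack([2 * rows, 2 * cols, np.ones_like(rows, dtype=float)])
    b = rows.astype(float) ** 2 + cols.astype(float) ** 2
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cy, cx, c = sol
    radius = float(np.sqrt(c + cy**2 + cx**2))
    return CircleFit(center=(float(cy), float(cx)), radius=radius)


def find_field_circle(pixels: np.ndarray, threshold: float = FOREGROUND_THRESHOLD) -> CircleFit:
    fg = (pixels > threshold).any(axis=2)
    if not fg.any():
        raise CircleFitError("no foreground pixels above threshold")
    labels = measure.label(fg)
    largest = labels == np.argmax(np.bincount(labels.ravel())[1:]) + 1
    boundary = largest ^ morphology.erosion(largest)
    rows, cols = np.nonzero(boundary)
    if len(rows) < 3:
        raise CircleFitError("foreground too small to fit a circle")
    fit = fit_circle_lsq(rows, cols)
    # boundary pixel centers lie ~half a pixel inside the continuous circle
    return CircleFit(center=fit.center, radius=fit.radius + 0.5)


def crop_to_square(pixels: np.ndarray, side: int = 512) -> tuple[np.ndarray, CircleFit]:
    """Crop the fitted retinal circle's bounding square and resample.

    Returns the side x side image (float, unit scale) and the fitted
    circle in original-image coordinates.  Regions of the bounding square
    outside the image are padded with black so the circle stays centered.
    """
    pixels = np.asarray(pixels, dtype=np.float32)
    circle = find_field_circle(pixels)
    cy, cx = circle.center
    r = circle.radius
    h, w = pixels.shape[:2]
    top, left = int(np.floor(cy - r)), int(np.floor(cx - r))
    size = int(np.ceil(2 * r))
    square = np.zeros((size, size, pixels.shape[2]), np.float32)
    src_t, src_l = max(top, 0), max(left, 0)
    src_b, src_r = min(top + size, h), min(left + size, w)
    square[src_t - top : src_b - top, src_l - left : src_r - left] = pixels[
        src_t:src_b, src_l:src_r
    ]
    out = transform.resize(
        square, (side, side), order=1, mode="constant", anti_aliasing=False,
        preserve_range=True,
    ).astype(np.float32)
    return out, circle


def fit_normalization(images: list[np.ndarray]) -> NormalizationStats:
    """Pooled per-channel mean/std over every pixel of every training image."""
    if not images:
        raise ValueError("empty training collection")
    n_total = 0
    s1 = np.zeros(3, np.float64)
    s2 = np.zeros(3, np.float64)
    for img in images:
        flat = img.reshape(-1, img.shape[2]).astype(np.float64)
        n_total += flat.shape[0]
        s1 += flat.sum(axis=0)
        s2 += (flat**2).sum(axis=0)
    mean = s1 / n_total
    var = s2 / n_total - mean**2
    var = np.maximum(var, 0.0)
    std = np.sqrt(var)
    if np.any(std == 0):
        raise ZeroStdError(f"constant-valued channel(s): {np.nonzero(std == 0)[0].tolist()}")
    return NormalizationStats(mean=mean, std=std)


def apply_normalization(image: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    return ((image - stats.mean) / stats.std).astype(np.float32)


def invert_normalization(image: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    return (image * stats.std + stats.mean).astype(np.float32)
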