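"""Human-facing explanations from evidence maps.

Three views, mirroring how a screener would consume them: a full-resolution
heatmap overlay (map values placed at their patch centers and bilinearly
interpolated), up to twelve receptive-field-sized bounding boxes around the
strictly positive evidence peaks, and the ranked patch crops behind those
boxes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .model import CLASS_DR, EvidenceMap

DEFAULT_K_MAX = 12


@dataclass(frozen=True)
class BoundingBox:
    """Receptive-field-sized square, 0-based top-left input-pixel coords."""

    row: int
    col: int
    side: int
    score: float
    rank: int

    def contains_any(self, mask: np.ndarray) -> bool:
        return bool(mask[self.row : self.row + self.side, self.col : self.col + self.side].any())


@dataclass
class ExplanationSet:
    image_id: str
    boxes: list
    class_explained: int = CLASS_DR
    overlay: np.ndarray | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "image_id": self.image_id,
                "class_explained": int(self.class_explained),
                "boxes": [
                    {
                        "row": b.row, "col": b.col, "side": b.side,
                        "score": b.score, "rank": b.rank,
                    }
                    for b in self.boxes
                ],
            },
            indent=2,
        )


def upsample_overlay(
    emap: EvidenceMap, class_index: int, target_size: tuple[int, int] | None = None
) -> np.ndarray:
    """Full-resolution heatmap: cell values sit at patch centers
    (i*s + (q-1)/2), bilinear between centers, edge-clamped outside."""
    if not 0 <= class_index < emap.n_classes:
        raise IndexError(f"class index {class_index} out of range")
    target_size = target_size or emap.input_size
    if target_size != emap.input_size:
        raise ValueError("overlay target size must equal the source image size")
    h, w = target_size
    c0 = (emap.patch - 1) / 2.0
    rows = (np.arange(h) - c0) / emap.stride
    cols = (np.arange(w) - c0) / emap.stride
    grid = np.meshgrid(rows, cols, indexing="ij")
    vals = emap.values[:, :, class_index]
    return map_coordinates(vals, grid, order=1, mode="nearest")


def extract_boxes(
    emap: EvidenceMap, class_index: int = CLASS_DR, k_max: int = DEFAULT_K_MAX,
    image_id: str = "", with_overlay: bool = False,
) -> ExplanationSet:
    """Greedy peak picking with center suppression.

    Repeatedly select the cell with the highest strictly positive evidence
    (ties broken row-major), emit its patch rectangle, then suppress every
    cell whose patch center lies within q/2 pixels (Chebyshev) of the
    selected center.  Stops at `k_max` boxes or when no positive cell is
    left; an empty set is a valid explanation of a clean image.
    """
    vals = emap.values[:, :, class_index].copy()
    q, s = emap.patch, emap.stride
    gh, gw = vals.shape
    ii, jj = np.mgrid[0:gh, 0:gw]
    centers_r = ii * s + (q - 1) / 2.0
    centers_c = jj * s + (q - 1) / 2.0
    alive = vals > 0.0
    boxes = []
    while len(boxes) < k_max and alive.any():
        masked = np.where(alive, vals, -np.inf)
        flat = int(np.argmax(masked))  # first max in row-major order
        bi, bj = divmod(flat, gw)
        score = float(vals[bi, bj])
        row, col, side = emap.patch_extent(bi, bj)
        boxes.append(BoundingBox(row=row, col=col, side=side, score=score, rank=len(boxes) + 1))
        cheb = np.maximum(
            np.abs(centers_r - centers_r[bi, bj]), np.abs(centers_c - centers_c[bi, bj])
        )
        alive &= cheb > q / 2.0
    overlay = upsample_overlay(emap, class_index) if with_overlay else None
    return ExplanationSet(
        image_id=image_id, boxes=boxes, class_explained=class_index, overlay=overlay
    )


def rank_patches(image: np.ndarray, explanation: ExplanationSet) -> list[np.ndarray]:
    """Pixel crops of each box, highest evidence first."""
    ordered = sorted(explanation.boxes, key=lambda b: b.rank)
    crops = []
    for box in ordered:
        if box.row < 0 or box.col < 0 or box.row + box.side > image.shape[0] or box.col + box.side > image.shape[1]:
            raise ValueError("box outside image bounds")
        crops.append(image[box.row : box.row + box.side, box.col : box.col + box.side].copy())
    return crops
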