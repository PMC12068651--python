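"""File round-trips: PNG images and masks, CSV metadata, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw


def write_png(path, image: np.ndarray) -> None:
    """Unit-scale float (H, W, 3) -> 8-bit RGB PNG."""
    arr = np.clip(np.asarray(image) * 255.0 + 0.5, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def read_png(path) -> np.ndarray:
    """8-bit PNG/JPEG -> unit-scale float32 (H, W, 3)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float32)
    return arr / 255.0


def write_mask_png(path, mask: np.ndarray) -> None:
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8), mode="L").save(path)


def read_mask_png(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 127


def overlay_png(path, image: np.ndarray, heatmap: np.ndarray, alpha: float = 0.5) -> None:
    """Burn a signed false-colour heatmap (red = positive evidence) onto the image."""
    hm = np.asarray(heatmap, dtype=float)
    scale = np.abs(hm).max() or 1.0
    norm = hm / scale
    color = np.zeros(image.shape, dtype=float)
    color[..., 0] = np.clip(norm, 0, 1)  # evidence for disease
    color[..., 2] = np.clip(-norm, 0, 1)  # evidence against
    write_png(path, (1 - alpha) * image + alpha * color)


def boxes_png(path, image: np.ndarray, explanation, width: int = 1) -> None:
    arr = np.clip(np.asarray(image) * 255.0 + 0.5, 0, 255).astype(np.uint8)
    im = Image.fromarray(arr, mode="RGB")
    draw = ImageDraw.Draw(im)
    for box in explanation.boxes:
        draw.rectangle(
            [box.col, box.row, box.col + box.side - 1, box.row + box.side - 1],
            outline=(40, 90, 255), width=width,
        )
    im.save(path)


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def point_annotations_to_mask(
    points: list[tuple[int, int]], shape: tuple[int, int], radius: int = 5
) -> np.ndarray:
    """Grader click locations -> mask (each click dilated to a 5-px disc)."""
    mask = np.zeros(shape, bool)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for r, c in points:
        mask |= (rr - r) ** 2 + (cc - c) ** 2 <= radius**2
    return mask
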