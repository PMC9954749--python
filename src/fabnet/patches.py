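"""Class-balanced patch budgeting and seeded random patch extraction.

Datasets like BreakHis are imbalanced (e.g. ductal carcinoma dominates), so
the number of patches drawn from each image is scaled inversely to its
class's image count: a class with x_i images receives

    N_i = ceil( mean_j(x_j) / x_i * beta )

patches per image, which makes the per-class patch totals N_i * x_i nearly
equal (up to ceiling error). beta (default 32) sets the overall budget:
a perfectly balanced dataset gets exactly beta patches per image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PatchBudget",
    "PatchRecord",
    "PatchError",
    "compute_patch_budget",
    "extract_patches",
    "resize_bilinear",
    "write_patch_manifest",
    "read_patch_manifest",
]

DEFAULT_PATCH_SIZE = 224
DEFAULT_BETA = 32

PATCH_MANIFEST_COLUMNS = [
    "patch_id",
    "source_image_id",
    "patient_id",
    "class_label",
    "magnification",
    "x",
    "y",
    "size",
    "path",
]


class PatchError(ValueError):
    pass


@dataclass(frozen=True)
class PatchBudget:
    """Per-class patches-per-image quota."""

    per_class: dict[str, int]
    beta: int
    class_counts: dict[str, int]

    @property
    def n_classes(self) -> int:
        return len(self.class_counts)

    def total_patches(self, cls: str) -> int:
        return self.per_class[cls] * self.class_counts[cls]


@dataclass(frozen=True)
class PatchRecord:
    patch_id: str
    source_image_id: str
    patient_id: str
    class_label: str
    magnification: str
    x: int
    y: int
    size: int

    def __post_init__(self):
        if self.x < 0 or self.y < 0 or self.size < 1:
            raise PatchError("patch window must be a positive box at nonnegative offsets")


def compute_patch_budget(class_counts: dict[str, int], beta: int = DEFAULT_BETA) -> PatchBudget:
    """Patches per image for each class: N_i = ceil(mean(x)/x_i * beta).

    Exact integer arithmetic: N_i = ceil(S * beta / (n * x_i)) with
    S = sum of class counts and n the number of classes.

    Raises :class:`PatchError` if any class has zero images.
    """
    if not class_counts:
        raise PatchError("class_counts is empty")
    if beta < 1:
        raise PatchError("beta must be a positive integer")
    for cls, x in class_counts.items():
        if x <= 0:
            raise PatchError(f"class {cls!r} has no images (x_i = {x})")
    s = sum(class_counts.values())
    n = len(class_counts)
    per_class = {cls: -(-s * beta // (n * x)) for cls, x in class_counts.items()}
    return PatchBudget(per_class=per_class, beta=beta, class_counts=dict(class_counts))


def extract_patches(
    image: np.ndarray,
    budget_for_class: int,
    size: int = DEFAULT_PATCH_SIZE,
    seed: int = 0,
    source_image_id: str = "",
    patient_id: str = "",
    class_label: str = "",
    magnification: str = "none",
) -> tuple[list[PatchRecord], list[np.ndarray]]:
    """Draw ``budget_for_class`` random in-bounds windows from one image.

    Offsets are uniform over the valid placements (0-based, half-open
    windows), deterministic under ``seed``. Raises :class:`PatchError` when
    the image is smaller than the window in either axis — images are never
    silently upscaled.
    """
    h, w = image.shape[:2]
    if h < size or w < size:
        raise PatchError(f"image ({h}x{w}) smaller than patch size {size}")
    if budget_for_class < 1:
        raise PatchError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    xs = rng.integers(0, w - size + 1, size=budget_for_class)
    ys = rng.integers(0, h - size + 1, size=budget_for_class)
    records, pixels = [], []
    for k, (x, y) in enumerate(zip(xs, ys)):
        records.append(
            PatchRecord(
                patch_id=f"{source_image_id}_p{k:03d}",
                source_image_id=source_image_id,
                patient_id=patient_id,
                class_label=class_label,
                magnification=magnification,
                x=int(x),
                y=int(y),
                size=size,
            )
        )
        pixels.append(image[y : y + size, x : x + size].copy())
    return records, pixels


def resize_bilinear(image: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resize (whole-image mode, e.g. 700x460 -> 224x224)."""
    img = np.asarray(image, dtype=float)
    h, w = img.shape[:2]
    ys = (np.arange(out_h) + 0.5) * h / out_h - 0.5
    xs = (np.arange(out_w) + 0.5) * w / out_w - 0.5
    ys = np.clip(ys, 0, h - 1)
    xs = np.clip(xs, 0, w - 1)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    wy = (ys - y0)[:, None, None]
    wx = (xs - x0)[None, :, None]
    if img.ndim == 2:
        img = img[:, :, None]
        squeeze = True
    else:
        squeeze = False
    top = img[y0][:, x0] * (1 - wx) + img[y0][:, x1] * wx
    bot = img[y1][:, x0] * (1 - wx) + img[y1][:, x1] * wx
    out = top * (1 - wy) + bot * wy
    if squeeze:
        out = out[:, :, 0]
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def write_patch_manifest(records: list[PatchRecord], paths: list[str], out_csv: str | Path) -> None:
    rows = []
    for rec, p in zip(records, paths):
        row = rec.__dict__.copy()
        row["path"] = p
        rows.append(row)
    pd.DataFrame(rows, columns=PATCH_MANIFEST_COLUMNS).to_csv(out_csv, index=False)


def read_patch_manifest(csv_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(csv_path, dtype={"patch_id": str, "source_image_id": str, "patient_id": str})
    missing = set(PATCH_MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise PatchError(f"patch manifest missing columns: {sorted(missing)}")
    return df
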