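"""Seeded synthetic H&E-like images and cohort trees with known ground truth.

Images are rendered through the same Beer–Lambert optics the stain module
assumes: a hematoxylin and an eosin concentration field are mixed through a
ground-truth stain matrix and exponentiated to RGB. Each class is
characterized by its nuclear density and nucleus size — elliptical,
hematoxylin-dominant nuclei over a smoothly varying eosin background — so
classes are separable by nuclear content, stain vectors are recoverable, and
the normalization fixed-point holds by construction. Magnification is
emulated as a nucleus scale factor only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .cohort import SampleRecord, write_manifest
from .stain import DEFAULT_REFERENCE, StainMatrix, od_to_rgb

__all__ = [
    "SyntheticClassSpec",
    "SyntheticCohortConfig",
    "MAGNIFICATION_SCALE",
    "generate_tissue_image",
    "generate_cohort",
    "render_concentrations",
    "two_class_specs",
]

MAGNIFICATION_SCALE = {"40X": 0.5, "100X": 1.0, "200X": 1.5, "400X": 2.0, "none": 1.0}


@dataclass(frozen=True)
class SyntheticClassSpec:
    """Appearance parameters of one synthetic tissue class."""

    name: str
    nucleus_density: float          # expected nuclei per 100x100 px
    nucleus_radius: tuple[float, float] = (4.0, 8.0)
    eosin_background_level: float = 0.35   # background eosin concentration
    category: str = "none"          # benign | malignant | none

    def __post_init__(self):
        if self.nucleus_density < 0:
            raise ValueError("nucleus density must be >= 0")
        lo, hi = self.nucleus_radius
        if lo <= 0 or hi < lo:
            raise ValueError("nucleus radius range must be positive and ordered")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    classes: tuple[SyntheticClassSpec, ...]
    patients_per_class: int = 3
    images_per_patient: int = 4
    magnifications: tuple[str, ...] = ("none",)
    image_size: int = 96
    stains: StainMatrix = DEFAULT_REFERENCE
    seed: int = 0

    def __post_init__(self):
        if self.patients_per_class < 1 or self.images_per_patient < 1:
            raise ValueError("cohort dimensions must be positive")
        for m in self.magnifications:
            if m not in MAGNIFICATION_SCALE:
                raise ValueError(f"unknown magnification {m!r}")


def two_class_specs(
    densities: tuple[float, float] = (5.0, 50.0),
    names: tuple[str, str] = ("sparse", "dense"),
) -> tuple[SyntheticClassSpec, SyntheticClassSpec]:
    """Two classes separated by nuclear density (benign-like vs malignant-like)."""
    return (
        SyntheticClassSpec(name=names[0], nucleus_density=densities[0], category="benign"),
        SyntheticClassSpec(name=names[1], nucleus_density=densities[1], category="malignant"),
    )


def _smooth_field(
    rng: np.random.Generator, h: int, w: int, lo: float, hi: float, coarse: int = 6
) -> np.ndarray:
    """Low-frequency random field in [lo, hi] via bilinear upsampling."""
    grid = rng.uniform(lo, hi, size=(coarse + 1, coarse + 1))
    ys = np.linspace(0, coarse, h)
    xs = np.linspace(0, coarse, w)
    y0 = np.minimum(ys.astype(int), coarse - 1)
    x0 = np.minimum(xs.astype(int), coarse - 1)
    wy = (ys - y0)[:, None]
    wx = (xs - x0)[None, :]
    g = grid
    return (
        g[y0][:, x0] * (1 - wy) * (1 - wx)
        + g[y0][:, x0 + 1] * (1 - wy) * wx
        + g[y0 + 1][:, x0] * wy * (1 - wx)
        + g[y0 + 1][:, x0 + 1] * wy * wx
    )


def generate_tissue_image(
    class_spec: SyntheticClassSpec,
    stains: StainMatrix = DEFAULT_REFERENCE,
    size: int = 96,
    seed: int = 0,
    magnification: str = "none",
) -> tuple[np.ndarray, dict]:
    """Render one synthetic H&E-like image; returns (RGB uint8, truth).

    The truth record carries the nucleus count and the exact hematoxylin and
    eosin concentration fields used for rendering.
    """
    rng = np.random.default_rng(seed)
    h = w = int(size)
    scale = MAGNIFICATION_SCALE[magnification]

    c_e = class_spec.eosin_background_level * _smooth_field(rng, h, w, 0.7, 1.3)
    c_h = np.zeros((h, w))

    n_nuclei = int(rng.poisson(class_spec.nucleus_density * h * w / 1.0e4))
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_nuclei):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        r_lo, r_hi = class_spec.nucleus_radius
        ry = rng.uniform(r_lo, r_hi) * scale
        rx = rng.uniform(r_lo, r_hi) * scale
        theta = rng.uniform(0, np.pi)
        amp = rng.uniform(0.8, 1.2)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) - dx * np.sin(theta)
        v = dy * np.sin(theta) + dx * np.cos(theta)
        inside = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
        c_h[inside] = np.maximum(c_h[inside], amp)
        c_e[inside] *= 0.1  # nuclei displace the eosin-stained cytoplasm

    rgb = render_concentrations(c_h, c_e, stains)
    truth = {"nucleus_count": n_nuclei, "c_h": c_h, "c_e": c_e, "class": class_spec.name}
    return rgb, truth


def render_concentrations(
    c_h: np.ndarray, c_e: np.ndarray, stains: StainMatrix
) -> np.ndarray:
    """Beer–Lambert rendering of concentration fields to 8-bit RGB."""
    conc = np.stack([c_h, c_e], axis=-1)
    od = conc @ stains.matrix.T
    return od_to_rgb(od)


def generate_cohort(
    config: SyntheticCohortConfig,
    out_root: str | Path,
    style: str = "breakhis",
) -> list[SampleRecord]:
    """Write a synthetic cohort tree plus manifest; returns the records.

    ``style='breakhis'`` writes ``category/class/patient/magnification/*.png``;
    ``style='class_folder'`` writes ``class/*.png``. Nucleus-count ground
    truth is written as a JSON sidecar next to the manifest. Deterministic at
    byte level for a fixed config seed.
    """
    if style not in ("breakhis", "class_folder"):
        raise ValueError(f"unknown cohort style {style!r}")
    out_root = Path(out_root)
    out_root.mkdir(parents=True, exist_ok=True)
    records: list[SampleRecord] = []
    truth: dict[str, int] = {}
    for ci, cls in enumerate(config.classes):
        for pi in range(config.patients_per_class):
            patient = f"{cls.name}_pt{pi + 1:02d}"
            for ii in range(config.images_per_patient):
                for mi, mag in enumerate(config.magnifications):
                    seed = np.random.SeedSequence(
                        [config.seed, ci, pi, ii, mi]
                    ).generate_state(1)[0]
                    rgb, t = generate_tissue_image(
                        cls,
                        stains=config.stains,
                        size=config.image_size,
                        seed=int(seed),
                        magnification=mag,
                    )
                    image_id = f"{cls.name}_{patient}_{mag}_{ii + 1:03d}"
                    if style == "breakhis":
                        d = out_root / cls.category / cls.name / patient / mag
                    else:
                        d = out_root / cls.name
                    d.mkdir(parents=True, exist_ok=True)
                    path = d / f"{image_id}.png"
                    Image.fromarray(rgb).save(path)
                    truth[image_id] = t["nucleus_count"]
                    records.append(
                        SampleRecord(
                            image_id=image_id,
                            path=str(path),
                            patient_id=patient if style == "breakhis" else f"{cls.name}_{image_id}",
                            category=cls.category if style == "breakhis" else "none",
                            subclass=cls.name,
                            magnification=mag if style == "breakhis" else "none",
                        )
                    )
    write_manifest(records, out_root / "manifest.csv")
    (out_root / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return records
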