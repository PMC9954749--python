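"""Macenko stain normalization for H&E histology images.

Stain mixing is approximately linear in optical density (Beer–Lambert), so
an RGB image is mapped to OD space, the two dominant stain directions are
estimated from the extreme angles of the tissue-pixel cloud in the principal
plane, per-pixel hematoxylin/eosin concentrations are recovered by least
squares, and the image is re-rendered against a fixed reference basis with
its concentration range rescaled. This removes scanner- and lab-dependent
color variation before classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "StainMatrix",
    "StainError",
    "NoTissueError",
    "DegenerateStainError",
    "DEFAULT_REFERENCE",
    "DEFAULT_REFERENCE_MAX_C",
    "rgb_to_od",
    "od_to_rgb",
    "estimate_stain_matrix",
    "compute_concentrations",
    "normalize_image",
    "angular_distance_degrees",
]

I0 = 255.0  # incident intensity for the Beer–Lambert transform


class StainError(ValueError):
    pass


class NoTissueError(StainError):
    """Too few pixels above the OD threshold to estimate stains."""


class DegenerateStainError(StainError):
    """The OD pixel cloud does not span two stain directions."""


@dataclass(frozen=True)
class StainMatrix:
    """Unit OD color vectors of the two stains, hematoxylin first.

    ``matrix`` has shape (3, 2): columns are the H and E vectors. The vector
    with the larger blue-channel OD component is hematoxylin (hematoxylin
    absorbs red/green and transmits blue weakly, i.e. nuclei look blue).
    """

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 2):
            raise StainError(f"stain matrix must be 3x2, got {m.shape}")
        norms = np.linalg.norm(m, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise StainError("stain vectors must be unit length")
        if np.any(m < -1e-9):
            raise StainError("stain vector components must be nonnegative")
        if m[2, 0] < m[2, 1]:
            raise StainError("hematoxylin (larger blue OD) must be the first column")
        object.__setattr__(self, "matrix", m)

    @property
    def hematoxylin(self) -> np.ndarray:
        return self.matrix[:, 0]

    @property
    def eosin(self) -> np.ndarray:
        return self.matrix[:, 1]

    @classmethod
    def from_vectors(cls, v1, v2) -> "StainMatrix":
        """Normalize, and order the two OD vectors (H = larger blue OD)."""
        v1 = np.asarray(v1, float)
        v2 = np.asarray(v2, float)
        v1 = v1 / np.linalg.norm(v1)
        v2 = v2 / np.linalg.norm(v2)
        if v1[2] >= v2[2]:
            m = np.column_stack([v1, v2])
        else:
            m = np.column_stack([v2, v1])
        return cls(m)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.matrix.T.ravel().tolist()))

    @classmethod
    def from_json(cls, path: str | Path) -> "StainMatrix":
        vals = json.loads(Path(path).read_text())
        m = np.asarray(vals, float).reshape(2, 3).T
        return cls(m)


DEFAULT_REFERENCE = StainMatrix.from_vectors((0.65, 0.70, 0.29), (0.07, 0.99, 0.11))
DEFAULT_REFERENCE_MAX_C = np.array([1.9, 1.0])


def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """Optical density of an 8-bit RGB image: OD = -log10((I+1)/I0).

    The +1 guards against log(0) at I = 0; background (I = 254) maps to 0.
    """
    img = np.asarray(image, dtype=float)
    if img.min() < 0 or img.max() > 255:
        raise StainError("pixel values must lie in [0, 255]")
    return -np.log10((img + 1.0) / I0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, rounded and clipped to valid 8-bit RGB."""
    img = I0 * np.power(10.0, -np.asarray(od, float)) - 1.0
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def angular_distance_degrees(u, v) -> float:
    """Angle between two vectors (sign-insensitive), in degrees."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    c = abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def estimate_stain_matrix(
    image: np.ndarray,
    od_threshold: float = 0.15,
    angle_percentile: float = 1.0,
    min_tissue_pixels: int = 100,
) -> StainMatrix:
    """Estimate the two-stain OD basis of an H&E image (Macenko).

    Pixels with every channel's OD at or below ``od_threshold`` are treated
    as background and discarded. The two leading eigenvectors of the retained
    OD cloud's covariance define the stain plane; the directions at the
    ``angle_percentile``-th and (100 - ``angle_percentile``)-th percentile
    angles within that plane are taken as the stain vectors.

    Raises
    ------
    NoTissueError
        Fewer than ``min_tissue_pixels`` tissue pixels.
    DegenerateStainError
        The cloud is effectively one-dimensional (single stain).
    """
    od = rgb_to_od(image).reshape(-1, 3)
    tissue = od[(od > od_threshold).any(axis=1)]
    if tissue.shape[0] < min_tissue_pixels:
        raise NoTissueError(
            f"only {tissue.shape[0]} tissue pixels above OD {od_threshold} "
            f"(need {min_tissue_pixels})"
        )
    cov = np.cov(tissue, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    # eigh returns ascending order; take the two largest
    if evals[-1] <= 0 or evals[-2] / evals[-1] < 1e-4:
        raise DegenerateStainError("OD covariance is effectively rank 1")
    plane = evecs[:, [-1, -2]]  # 3x2
    # orient the plane axes so projections are mostly positive
    proj = tissue @ plane
    for j in range(2):
        if proj[:, j].sum() < 0:
            plane[:, j] *= -1
            proj[:, j] *= -1
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo = np.percentile(angles, angle_percentile)
    hi = np.percentile(angles, 100.0 - angle_percentile)
    if np.degrees(hi - lo) < 1.0:
        raise DegenerateStainError(
            f"stain angle spread {np.degrees(hi - lo):.3f} deg is below 1 deg"
        )
    v_lo = plane @ np.array([np.cos(lo), np.sin(lo)])
    v_hi = plane @ np.array([np.cos(hi), np.sin(hi)])
    vectors = []
    for v in (v_lo, v_hi):
        if v.sum() < 0:
            v = -v
        vectors.append(np.clip(v, 0.0, None))
    return StainMatrix.from_vectors(*vectors)


def compute_concentrations(od: np.ndarray, stains: StainMatrix) -> np.ndarray:
    """Per-pixel least-squares stain concentrations, clipped at zero.

    ``od`` may be (..., 3); the result has shape (..., 2) with the
    hematoxylin concentration first.
    """
    od = np.asarray(od, float)
    flat = od.reshape(-1, 3)
    c, *_ = np.linalg.lstsq(stains.matrix, flat.T, rcond=None)
    c = np.clip(c.T, 0.0, None)
    return c.reshape(od.shape[:-1] + (2,))


def normalize_image(
    image: np.ndarray,
    reference: StainMatrix = DEFAULT_REFERENCE,
    reference_max_c: np.ndarray = DEFAULT_REFERENCE_MAX_C,
    od_threshold: float = 0.15,
    angle_percentile: float = 1.0,
    scale_percentile: float = 99.0,
) -> np.ndarray:
    """Map an image's stain basis and concentration range onto a reference.

    Estimates the source stains, solves for concentrations, rescales each
    stain channel so its ``scale_percentile``-th percentile concentration
    matches ``reference_max_c``, and re-renders through the reference basis.
    Propagates :class:`NoTissueError` / :class:`DegenerateStainError`.
    """
    stains = estimate_stain_matrix(
        image, od_threshold=od_threshold, angle_percentile=angle_percentile
    )
    od = rgb_to_od(image)
    conc = compute_concentrations(od, stains)
    flat = conc.reshape(-1, 2)
    src_max = np.percentile(flat, scale_percentile, axis=0)
    src_max = np.where(src_max <= 1e-8, 1.0, src_max)
    scaled = flat * (np.asarray(reference_max_c, float) / src_max)
    od_new = scaled @ reference.matrix.T
    return od_to_rgb(od_new.reshape(image.shape))
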