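"""Dataset manifests, directory scanning, and patient-aware partitioning.

Two on-disk layouts are supported:

* a BreakHis-style tree ``category/subclass/patient/magnification/image.png``
  (benign/malignant, four histological subtypes each, four magnifications),
* a class-folder tree ``class/image.png`` (NCT-CRC style, nine tissue
  classes, no patient structure — each image becomes its own pseudo-patient,
  so image-level and patient-level metrics coincide there).

Splitting is always at the patient level: no patient contributes images to
both sides of the 70:30 train/test split or to two folds of the
cross-validation, which rules out leakage between training and evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SampleRecord",
    "SplitPlan",
    "CVFolds",
    "CohortError",
    "TaxonomyError",
    "BREAKHIS_TAXONOMY",
    "CRC_CLASSES",
    "BREAKHIS_CENSUS",
    "MAGNIFICATIONS",
    "scan_breakhis_tree",
    "scan_class_folder_tree",
    "make_patient_split",
    "make_cv_folds",
    "write_manifest",
    "read_manifest",
    "breakhis_census_manifest",
    "census",
]

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}
MAGNIFICATIONS = ("40X", "100X", "200X", "400X")

BREAKHIS_TAXONOMY = {
    "benign": ("ADE", "FID", "PHT", "TUA"),
    "malignant": ("DUC", "LOC", "MUC", "PAC"),
}
CRC_CLASSES = ("ADI", "BACK", "DEB", "LYM", "MUC", "MUS", "NORM", "STR", "TUM")

# Printed census of the BreakHis cohort: per-subclass image counts at the
# four magnifications, plus the number of individuals per subclass. Totals:
# 7909 images over 82 patients.
BREAKHIS_CENSUS = {
    "PHT": {"category": "benign", "counts": (149, 150, 140, 130), "patients": 7},
    "FID": {"category": "benign", "counts": (253, 260, 264, 237), "patients": 10},
    "ADE": {"category": "benign", "counts": (114, 113, 111, 106), "patients": 4},
    "TUA": {"category": "benign", "counts": (109, 121, 108, 115), "patients": 3},
    "PAC": {"category": "malignant", "counts": (145, 142, 135, 138), "patients": 6},
    "DUC": {"category": "malignant", "counts": (864, 903, 896, 788), "patients": 38},
    "LOC": {"category": "malignant", "counts": (156, 170, 163, 137), "patients": 5},
    "MUC": {"category": "malignant", "counts": (205, 222, 196, 169), "patients": 9},
}

MANIFEST_COLUMNS = ["image_id", "path", "patient_id", "category", "subclass", "magnification"]


class CohortError(ValueError):
    pass


class TaxonomyError(CohortError):
    pass


@dataclass(frozen=True)
class SampleRecord:
    image_id: str
    path: str
    patient_id: str
    category: str   # benign | malignant | none
    subclass: str
    magnification: str  # 40X | 100X | 200X | 400X | none


@dataclass(frozen=True)
class SplitPlan:
    train_patients: frozenset[str]
    test_patients: frozenset[str]
    ratio: float
    seed: int

    def __post_init__(self):
        if self.train_patients & self.test_patients:
            raise CohortError("train and test patient sets overlap")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "train_patients": sorted(self.train_patients),
                    "test_patients": sorted(self.test_patients),
                    "ratio": self.ratio,
                    "seed": self.seed,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        return cls(
            frozenset(d["train_patients"]),
            frozenset(d["test_patients"]),
            float(d["ratio"]),
            int(d["seed"]),
        )


@dataclass(frozen=True)
class CVFolds:
    k: int
    assignment: dict[str, int]  # patient -> fold index 0..k-1
    seed: int

    def fold_patients(self, fold: int) -> frozenset[str]:
        return frozenset(p for p, f in self.assignment.items() if f == fold)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"k": self.k, "assignment": self.assignment, "seed": self.seed}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CVFolds":
        d = json.loads(Path(path).read_text())
        return cls(int(d["k"]), {str(k): int(v) for k, v in d["assignment"].items()}, int(d["seed"]))


# ---------------------------------------------------------------------------
# directory scanning


def scan_breakhis_tree(root: str | Path, strict: bool = True) -> list[SampleRecord]:
    """Scan a ``category/subclass/patient/magnification/*.png`` tree.

    Records are returned in lexicographic path order. Unknown subclass
    directories raise :class:`TaxonomyError` in strict mode.
    """
    root = Path(root)
    records = []
    for img in sorted(root.rglob("*")):
        if not img.is_file() or img.suffix.lower() not in IMAGE_EXTENSIONS:
            continue
        try:
            mag, patient, subclass, category = (
                img.parent.name,
                img.parent.parent.name,
                img.parent.parent.parent.name,
                img.parent.parent.parent.parent.name,
            )
        except AttributeError:  # file too shallow in the tree
            continue
        if strict:
            if category not in BREAKHIS_TAXONOMY:
                raise TaxonomyError(f"unknown category directory {category!r} for {img}")
            if subclass not in BREAKHIS_TAXONOMY[category]:
                raise TaxonomyError(f"unknown subclass {subclass!r} under {category!r}")
            if mag not in MAGNIFICATIONS:
                raise TaxonomyError(f"unknown magnification directory {mag!r}")
        records.append(
            SampleRecord(
                image_id=img.stem,
                path=str(img),
                patient_id=patient,
                category=category,
                subclass=subclass,
                magnification=mag,
            )
        )
    return records


def scan_class_folder_tree(root: str | Path, strict: bool = True) -> list[SampleRecord]:
    """Scan a flat ``class/*.png`` tree (CRC style, no patient hierarchy).

    Each image becomes its own pseudo-patient. In strict mode the folder
    names must be the nine colorectal tissue classes.
    """
    root = Path(root)
    records = []
    for img in sorted(root.rglob("*")):
        if not img.is_file() or img.suffix.lower() not in IMAGE_EXTENSIONS:
            continue
        cls = img.parent.name
        if strict and cls not in CRC_CLASSES:
            raise TaxonomyError(f"unknown class folder {cls!r} for {img}")
        records.append(
            SampleRecord(
                image_id=img.stem,
                path=str(img),
                patient_id=f"{cls}_{img.stem}",
                category="none",
                subclass=cls,
                magnification="none",
            )
        )
    return records


# ---------------------------------------------------------------------------
# manifests and census


def write_manifest(records: list[SampleRecord], out_csv: str | Path) -> None:
    pd.DataFrame([asdict(r) for r in records], columns=MANIFEST_COLUMNS).to_csv(
        out_csv, index=False
    )


def read_manifest(csv_path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(csv_path, dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise CohortError(f"manifest missing columns: {sorted(missing)}")
    return [SampleRecord(**{c: row[c] for c in MANIFEST_COLUMNS}) for _, row in df.iterrows()]


def breakhis_census_manifest() -> list[SampleRecord]:
    """Expand the printed per-class census into a metadata-only manifest.

    Images are assigned round-robin to each subclass's patients; the
    per-subclass, per-magnification counts and the patient roster match the
    printed census exactly (paths are empty — this manifest carries counts,
    not pixels).
    """
    records = []
    for subclass, info in BREAKHIS_CENSUS.items():
        patients = [f"{subclass}_pt{p + 1:02d}" for p in range(info["patients"])]
        for mag, count in zip(MAGNIFICATIONS, info["counts"]):
            for i in range(count):
                records.append(
                    SampleRecord(
                        image_id=f"{subclass}_{mag}_{i + 1:04d}",
                        path="",
                        patient_id=patients[i % len(patients)],
                        category=info["category"],
                        subclass=subclass,
                        magnification=mag,
                    )
                )
    return records


def census(records: list[SampleRecord]) -> dict:
    """Totals of a manifest: overall/per-subclass image counts, patients."""
    df = pd.DataFrame([asdict(r) for r in records])
    if df.empty:
        return {"n_images": 0, "n_patients": 0, "per_subclass": {}, "per_magnification": {}}
    return {
        "n_images": int(len(df)),
        "n_patients": int(df["patient_id"].nunique()),
        "per_subclass": df.groupby("subclass").size().to_dict(),
        "per_magnification": df.groupby("magnification").size().to_dict(),
    }


# ---------------------------------------------------------------------------
# patient-level partitioning


def _patients_of(records: list[SampleRecord]) -> list[str]:
    return sorted({r.patient_id for r in records})


def make_patient_split(
    records: list[SampleRecord], ratio: float = 0.70, seed: int = 0
) -> SplitPlan:
    """Shuffle patients by seed and cut at round-half-up(ratio * n)."""
    patients = _patients_of(records)
    if len(patients) < 2:
        raise CohortError(f"need at least 2 patients to split, got {len(patients)}")
    if not 0.0 < ratio < 1.0:
        raise CohortError("ratio must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(patients))
    n_train = int(np.floor(ratio * len(patients) + 0.5))
    n_train = min(max(n_train, 1), len(patients) - 1)
    return SplitPlan(
        train_patients=frozenset(order[:n_train]),
        test_patients=frozenset(order[n_train:]),
        ratio=ratio,
        seed=seed,
    )


def make_cv_folds(records: list[SampleRecord], k: int = 5, seed: int = 0) -> CVFolds:
    """Patient-level k-fold partition with fold sizes differing by at most 1."""
    patients = _patients_of(records)
    if len(patients) < k:
        raise CohortError(f"need at least k={k} patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(patients))
    assignment = {p: i % k for i, p in enumerate(order)}
    return CVFolds(k=k, assignment=assignment, seed=seed)


def records_for_patients(records: list[SampleRecord], patients) -> list[SampleRecord]:
    keep = set(patients)
    return [r for r in records if r.patient_id in keep]
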