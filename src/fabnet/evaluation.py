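"""Patch/image/patient-level evaluation: accuracies, PRF, ROC/AUC, confusion.

Patch probabilities are aggregated to images by arithmetic mean of the
probability vectors (soft mean, then argmax). Patient-level accuracy is the
mean over patients of each patient's fraction of correctly classified
images; image-level accuracy is the plain fraction of correctly classified
images. Precision, recall and F1 are computed from one-vs-rest confusion
counts; multiclass results are reported per class and macro-averaged.

Note on orientation: the accuracy ratios are computed as correct/total.
Argmax ties break toward the lowest class index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PredictionRecord",
    "ConfusionCounts",
    "PatientScore",
    "EvaluationError",
    "aggregate_patch_to_image",
    "patient_level_accuracy",
    "image_level_accuracy",
    "precision_recall_f1",
    "confusion_counts",
    "confusion_matrix",
    "roc_curve_auc",
    "evaluate_predictions",
]


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class PredictionRecord:
    """A probability vector with full provenance lineage."""

    record_id: str       # patch_id at patch level, image_id at image level
    image_id: str
    patient_id: str
    true_label: int
    probabilities: tuple[float, ...]

    def __post_init__(self):
        p = np.asarray(self.probabilities, float)
        if p.ndim != 1 or np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
            raise EvaluationError(
                f"probabilities must be a simplex vector, got sum {p.sum():.6f}"
            )

    @property
    def predicted_label(self) -> int:
        # ties break toward the lowest class index (argmax contract)
        return int(np.argmax(self.probabilities))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise EvaluationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class PatientScore:
    patient_id: str
    n_images: int
    n_correct: int

    @property
    def score(self) -> float:
        return self.n_correct / self.n_images


def aggregate_patch_to_image(records: list[PredictionRecord]) -> list[PredictionRecord]:
    """Mean patch probability vector per image (then argmax downstream).

    The returned records are ordered by first appearance of each image.
    """
    if not records:
        raise EvaluationError("no patch records to aggregate")
    by_image: dict[str, list[PredictionRecord]] = {}
    order: list[str] = []
    for r in records:
        if r.image_id not in by_image:
            by_image[r.image_id] = []
            order.append(r.image_id)
        by_image[r.image_id].append(r)
    out = []
    for image_id in order:
        group = by_image[image_id]
        labels = {g.true_label for g in group}
        patients = {g.patient_id for g in group}
        if len(labels) > 1 or len(patients) > 1:
            raise EvaluationError(f"inconsistent provenance for image {image_id!r}")
        mean_p = np.mean([g.probabilities for g in group], axis=0)
        out.append(
            PredictionRecord(
                record_id=image_id,
                image_id=image_id,
                patient_id=group[0].patient_id,
                true_label=group[0].true_label,
                probabilities=tuple(mean_p),
            )
        )
    return out


def patient_level_accuracy(
    image_records: list[PredictionRecord],
) -> tuple[float, list[PatientScore]]:
    """Mean over patients of (correct images / total images) per patient."""
    if not image_records:
        raise EvaluationError("no image records to evaluate")
    by_patient: dict[str, list[PredictionRecord]] = {}
    for r in image_records:
        by_patient.setdefault(r.patient_id, []).append(r)
    scores = [
        PatientScore(
            patient_id=pid,
            n_images=len(group),
            n_correct=sum(1 for g in group if g.predicted_label == g.true_label),
        )
        for pid, group in sorted(by_patient.items())
    ]
    return float(np.mean([s.score for s in scores])), scores


def image_level_accuracy(image_records: list[PredictionRecord]) -> float:
    """Correctly classified images / total images."""
    if not image_records:
        raise EvaluationError("no image records to evaluate")
    correct = sum(1 for r in image_records if r.predicted_label == r.true_label)
    return correct / len(image_records)


def confusion_counts(
    records: list[PredictionRecord], positive_class: int
) -> ConfusionCounts:
    """One-vs-rest TP/FP/FN/TN counts for one class."""
    tp = fp = fn = tn = 0
    for r in records:
        pred_pos = r.predicted_label == positive_class
        true_pos = r.true_label == positive_class
        if pred_pos and true_pos:
            tp += 1
        elif pred_pos:
            fp += 1
        elif true_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def precision_recall_f1(counts: ConfusionCounts) -> tuple[float, float, float, bool]:
    """Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean.

    Zero-denominator cases return 0 for the affected metric; the returned
    flag is True when any metric was degenerate.
    """
    degenerate = False
    if counts.tp + counts.fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    if precision + recall == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1, degenerate


def confusion_matrix(records: list[PredictionRecord], n_classes: int) -> np.ndarray:
    """Row = true class, column = predicted class."""
    m = np.zeros((n_classes, n_classes), dtype=int)
    for r in records:
        if not (0 <= r.true_label < n_classes) or not (0 <= r.predicted_label < n_classes):
            raise EvaluationError(
                f"label outside class set of size {n_classes}: "
                f"true {r.true_label}, predicted {r.predicted_label}"
            )
        m[r.true_label, r.predicted_label] += 1
    return m


def roc_curve_auc(
    records: list[PredictionRecord], positive_class: int
) -> tuple[np.ndarray, float]:
    """ROC sweep over unique scores and trapezoidal AUC.

    The score of an item is its predicted probability of ``positive_class``.
    Returns an (n_points, 2) array of (FPR, TPR) pairs from (0,0) to (1,1)
    and the area under that curve. Raises when only one class is present.
    """
    scores = np.array([r.probabilities[positive_class] for r in records])
    truth = np.array([r.true_label == positive_class for r in records])
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROC needs both positive and negative items")
    order = np.argsort(-scores, kind="stable")
    scores, truth = scores[order], truth[order]
    # group ties: emit one point per distinct threshold
    distinct = np.where(np.diff(scores))[0]
    idx = np.r_[distinct, len(scores) - 1]
    tps = np.cumsum(truth)[idx]
    fps = (idx + 1) - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def evaluate_predictions(
    patch_records: list[PredictionRecord], n_classes: int
) -> dict:
    """Full metrics report: per-level accuracies, per-class PRF, AUCs.

    Aggregates patches -> images -> patients; returns a JSON-serializable
    dict. Per-class metrics are one-vs-rest at the image level, plus macro
    averages.
    """
    image_records = aggregate_patch_to_image(patch_records)
    pat_acc, patient_scores = patient_level_accuracy(image_records)
    per_class = {}
    aucs = {}
    for c in range(n_classes):
        counts = confusion_counts(image_records, c)
        p, r, f1, flag = precision_recall_f1(counts)
        per_class[str(c)] = {
            "precision": p,
            "recall": r,
            "f1": f1,
            "degenerate": flag,
            "tp": counts.tp,
            "fp": counts.fp,
            "fn": counts.fn,
            "tn": counts.tn,
        }
        try:
            _, auc = roc_curve_auc(image_records, c)
            aucs[str(c)] = auc
        except EvaluationError:
            aucs[str(c)] = None
    macro = {
        k: float(np.mean([v[k] for v in per_class.values()]))
        for k in ("precision", "recall", "f1")
    }
    return {
        "patch_level_accuracy": image_level_accuracy(patch_records),
        "image_level_accuracy": image_level_accuracy(image_records),
        "patient_level_accuracy": pat_acc,
        "patient_scores": [
            {"patient_id": s.patient_id, "n_images": s.n_images, "n_correct": s.n_correct, "score": s.score}
            for s in patient_scores
        ],
        "per_class": per_class,
        "macro": macro,
        "auc": aucs,
        "confusion_matrix": confusion_matrix(image_records, n_classes).tolist(),
    }


def write_metrics_report(report: dict, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "metrics.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    cm = pd.DataFrame(report["confusion_matrix"])
    cm.to_csv(out_dir / "confusion_matrix.csv", index=False)
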