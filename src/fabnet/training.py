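"""Training loop and patch-level prediction.

Trains a compiled network with softmax cross-entropy under the standard
protocol (Adam, learning rate 1e-3, fixed epoch count, no data
augmentation, no early stopping). Everything is seeded: batch shuffling
comes from the config seed, parameter initialization from the model seed, so
identical configs reproduce identical parameter trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import nn
from .architecture import ArchitectureSpec, FabNetModel, build_model
from .cohort import SplitPlan
from .evaluation import PredictionRecord

__all__ = [
    "TrainConfig",
    "TrainingError",
    "load_patch_dataset",
    "train_classifier",
    "predict_patches",
]


class TrainingError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol knobs (defaults follow the published protocol)."""

    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 16          # 64 for class-folder (CRC-style) cohorts
    optimizer: str = "adam"
    seed: int = 0
    loss: str = "categorical-cross-entropy"
    task: str = "binary"

    def __post_init__(self):
        if self.epochs < 1:
            raise TrainingError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise TrainingError("learning_rate must be positive")
        if self.batch_size < 1:
            raise TrainingError("batch_size must be >= 1")
        if self.loss != "categorical-cross-entropy":
            raise TrainingError(f"unsupported loss {self.loss!r}")
        if self.task not in ("binary", "multiclass"):
            raise TrainingError(f"unknown task {self.task!r}")


def _load_image(path: str) -> np.ndarray:
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"))
    except OSError as exc:
        raise TrainingError(f"cannot read image file {path!r}: {exc}") from exc


def load_patch_dataset(
    manifest: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Load patch pixels from a manifest with ``path`` and ``class_label``.

    Returns NCHW float images in [0,1], integer labels, and the sorted label
    vocabulary defining the label -> index mapping.
    """
    if manifest.empty:
        raise TrainingError("patch manifest is empty")
    vocab = sorted(manifest["class_label"].astype(str).unique())
    index = {c: i for i, c in enumerate(vocab)}
    images = np.stack(
        [_load_image(p).transpose(2, 0, 1) for p in manifest["path"]]
    ).astype(np.float64) / 255.0
    labels = manifest["class_label"].astype(str).map(index).to_numpy()
    return images, labels, vocab


def train_classifier(
    spec: ArchitectureSpec,
    x: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    label_vocab: list[str] | None = None,
    patient_ids: np.ndarray | None = None,
    split_plan: SplitPlan | None = None,
) -> tuple[FabNetModel, pd.DataFrame]:
    """Train a model on NCHW images ``x`` with integer labels ``y``.

    When a :class:`SplitPlan` is given together with per-sample
    ``patient_ids``, training refuses to see any test patient's data (the
    provenance audit hook). Returns the trained model and a per-epoch
    history with columns ``epoch``, ``loss``, ``accuracy``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, int)
    if x.shape[0] == 0:
        raise TrainingError("empty training set")
    if x.shape[0] != y.shape[0]:
        raise TrainingError("images and labels disagree in length")
    if y.min() < 0 or y.max() >= spec.head_classes:
        raise TrainingError(
            f"labels span {y.min()}..{y.max()} but the head has {spec.head_classes} classes"
        )
    if split_plan is not None:
        if patient_ids is None:
            raise TrainingError("split_plan audit requires patient_ids")
        leaked = sorted(set(patient_ids) & set(split_plan.test_patients))
        if leaked:
            raise TrainingError(f"test patients present in training data: {leaked}")

    model = build_model(spec, seed=config.seed)
    optimizer = nn.make_optimizer(config.optimizer, model.layers, config.learning_rate)
    rng = np.random.default_rng(config.seed)
    n = x.shape[0]
    history = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward(x[idx], training=True)
            loss, probs, dlogits = nn.softmax_cross_entropy(logits, y[idx])
            optimizer.zero_grad()
            model.backward(dlogits)
            optimizer.step()
            losses.append(loss)
            correct += int((probs.argmax(axis=1) == y[idx]).sum())
        history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "accuracy": correct / n}
        )
    model.classes_ = list(label_vocab) if label_vocab is not None else list(range(spec.head_classes))
    return model, pd.DataFrame(history)


def predict_patches(
    model: FabNetModel,
    x: np.ndarray,
    meta: pd.DataFrame,
    label_vocab: list[str] | None = None,
    batch_size: int = 64,
) -> list[PredictionRecord]:
    """Per-patch probability records with image/patient lineage.

    ``meta`` must carry ``patch_id``, ``source_image_id``, ``patient_id`` and
    ``class_label`` rows aligned with ``x``.
    """
    if len(meta) != x.shape[0]:
        raise TrainingError("meta rows and image count disagree")
    vocab = label_vocab if label_vocab is not None else getattr(model, "classes_", None)
    if vocab is None:
        raise TrainingError("a label vocabulary is required to map class labels")
    index = {str(c): i for i, c in enumerate(vocab)}
    probs = np.concatenate(
        [
            model.predict_proba(x[i : i + batch_size])
            for i in range(0, x.shape[0], batch_size)
        ]
    )
    records = []
    for (_, row), p in zip(meta.iterrows(), probs):
        label = str(row["class_label"])
        if label not in index:
            raise TrainingError(f"label {label!r} not in model vocabulary {vocab}")
        records.append(
            PredictionRecord(
                record_id=str(row["patch_id"]),
                image_id=str(row["source_image_id"]),
                patient_id=str(row["patient_id"]),
                true_label=index[label],
                probabilities=tuple(p / p.sum()),
            )
        )
    return records
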