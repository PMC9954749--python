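"""End-to-end pipeline: synthesize/normalize -> patch -> split -> train -> evaluate.

Each stage reads only the artifacts of earlier stages from the output
directory, logs what it wrote into a run-record JSON, and fails with a
stage-named error when an upstream artifact is missing. All stochastic
stages derive their seeds from the single pipeline seed, so two identical
configured runs produce identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .architecture import default_fabnet_spec, tiny_fabnet_spec
from .cohort import (
    SampleRecord,
    SplitPlan,
    make_cv_folds,
    make_patient_split,
    read_manifest,
    write_manifest,
)
from .evaluation import evaluate_predictions, write_metrics_report
from .patches import (
    compute_patch_budget,
    extract_patches,
    read_patch_manifest,
    write_patch_manifest,
)
from .stain import DEFAULT_REFERENCE, normalize_image
from .synthetic import SyntheticCohortConfig, generate_cohort, two_class_specs
from .training import TrainConfig, load_patch_dataset, predict_patches, train_classifier

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

ALL_STAGES = ("synth", "normalize", "patch", "split", "train", "evaluate")


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full pipeline run (YAML-serializable)."""

    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # synthetic cohort
    densities: tuple[float, float] = (5.0, 50.0)
    patients_per_class: int = 5
    images_per_patient: int = 3
    image_size: int = 96
    # patching
    beta: int = 8
    patch_size: int = 32
    # split
    ratio: float = 0.70
    # architecture ("tiny" reduced variant or the full "default" network)
    arch: str = "tiny"
    filters: tuple[int, ...] = (8, 16)
    reduce_cap: int = 8
    # training
    epochs: int = 25
    learning_rate: float = 1e-3
    batch_size: int = 16
    optimizer: str = "adam"

    def __post_init__(self):
        for s in self.stages:
            if s not in ALL_STAGES:
                raise PipelineError(f"unknown stage {s!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("stages", "densities", "filters"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["densities"] = list(self.densities)
        d["filters"] = list(self.filters)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _stage_seed(seed: int, stage: str) -> int:
    idx = ALL_STAGES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage {needed_by!r} needs {path.name} produced by stage {stage!r}; "
            "run that stage first"
        )
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run record."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, list[str]] = {}

    def log(stage: str, *paths: Path):
        artifacts.setdefault(stage, []).extend(str(p) for p in paths)

    manifest_csv = out / "cohort" / "manifest.csv"
    norm_manifest_csv = out / "normalized" / "manifest.csv"
    patch_manifest_csv = out / "patches" / "manifest.csv"
    split_json = out / "split.json"
    history_csv = out / "history.csv"
    model_npz = out / "model.npz"
    metrics_dir = out / "metrics"

    if "synth" in config.stages:
        cohort_cfg = SyntheticCohortConfig(
            classes=two_class_specs(config.densities),
            patients_per_class=config.patients_per_class,
            images_per_patient=config.images_per_patient,
            image_size=config.image_size,
            seed=_stage_seed(config.seed, "synth"),
        )
        generate_cohort(cohort_cfg, out / "cohort", style="breakhis")
        log("synth", manifest_csv)

    if "normalize" in config.stages:
        _require(manifest_csv, "synth", "normalize")
        records = read_manifest(manifest_csv)
        norm_records = []
        for rec in records:
            with Image.open(rec.path) as im:
                rgb = np.asarray(im.convert("RGB"))
            normed = normalize_image(rgb, reference=DEFAULT_REFERENCE)
            rel = Path(rec.path).relative_to(out / "cohort")
            dst = out / "normalized" / rel
            dst.parent.mkdir(parents=True, exist_ok=True)
            Image.fromarray(normed).save(dst)
            norm_records.append(SampleRecord(**{**rec.__dict__, "path": str(dst)}))
        write_manifest(norm_records, norm_manifest_csv)
        log("normalize", norm_manifest_csv)

    if "patch" in config.stages:
        src_csv = norm_manifest_csv if norm_manifest_csv.exists() else manifest_csv
        _require(src_csv, "synth", "patch")
        records = read_manifest(src_csv)
        class_counts: dict[str, int] = {}
        for r in records:
            class_counts[r.subclass] = class_counts.get(r.subclass, 0) + 1
        budget = compute_patch_budget(class_counts, beta=config.beta)
        patch_dir = out / "patches"
        patch_dir.mkdir(parents=True, exist_ok=True)
        base = _stage_seed(config.seed, "patch")
        all_records, all_paths = [], []
        for i, rec in enumerate(records):
            with Image.open(rec.path) as im:
                rgb = np.asarray(im.convert("RGB"))
            precs, pixels = extract_patches(
                rgb,
                budget.per_class[rec.subclass],
                size=config.patch_size,
                seed=int(np.random.SeedSequence([base, i]).generate_state(1)[0]),
                source_image_id=rec.image_id,
                patient_id=rec.patient_id,
                class_label=rec.subclass,
                magnification=rec.magnification,
            )
            for pr, px in zip(precs, pixels):
                p = patch_dir / f"{pr.patch_id}.png"
                Image.fromarray(px).save(p)
                all_records.append(pr)
                all_paths.append(str(p))
        write_patch_manifest(all_records, all_paths, patch_manifest_csv)
        log("patch", patch_manifest_csv)

    if "split" in config.stages:
        src_csv = norm_manifest_csv if norm_manifest_csv.exists() else manifest_csv
        _require(src_csv, "synth", "split")
        records = read_manifest(src_csv)
        plan = make_patient_split(records, ratio=config.ratio, seed=_stage_seed(config.seed, "split"))
        plan.to_json(split_json)
        log("split", split_json)

    label_vocab = None
    model = None
    if "train" in config.stages:
        _require(patch_manifest_csv, "patch", "train")
        _require(split_json, "split", "train")
        plan = SplitPlan.from_json(split_json)
        df = read_patch_manifest(patch_manifest_csv)
        train_df = df[df["patient_id"].isin(plan.train_patients)].reset_index(drop=True)
        x, y, label_vocab = load_patch_dataset(train_df)
        spec = _make_spec(config, head_classes=len(label_vocab))
        tc = TrainConfig(
            epochs=config.epochs,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            optimizer=config.optimizer,
            seed=_stage_seed(config.seed, "train"),
            task="binary" if len(label_vocab) == 2 else "multiclass",
        )
        model, history = train_classifier(
            spec,
            x,
            y,
            tc,
            label_vocab=label_vocab,
            patient_ids=train_df["patient_id"].to_numpy(),
            split_plan=plan,
        )
        history.to_csv(history_csv, index=False)
        model.save(model_npz)
        log("train", history_csv, model_npz)

    if "evaluate" in config.stages:
        _require(patch_manifest_csv, "patch", "evaluate")
        _require(split_json, "split", "evaluate")
        if model is None:
            raise PipelineError(
                "stage 'evaluate' needs a trained model from stage 'train'; "
                "run that stage first"
            )
        plan = SplitPlan.from_json(split_json)
        df = read_patch_manifest(patch_manifest_csv)
        test_df = df[df["patient_id"].isin(plan.test_patients)].reset_index(drop=True)
        if test_df.empty:
            raise PipelineError("stage 'evaluate': no test-patient patches available")
        x, _, _ = load_patch_dataset(test_df)
        records = predict_patches(model, x, test_df, label_vocab=label_vocab)
        report = evaluate_predictions(records, n_classes=len(label_vocab))
        write_metrics_report(report, metrics_dir)
        log("evaluate", metrics_dir / "metrics.json", metrics_dir / "confusion_matrix.csv")

    record = {"seed": config.seed, "stages": list(config.stages), "artifacts": artifacts}
    (out / "run_record.json").write_text(json.dumps(record, indent=2, sort_keys=True))
    return record


def _make_spec(config: PipelineConfig, head_classes: int):
    if config.arch == "tiny":
        return tiny_fabnet_spec(
            head_classes=head_classes,
            filters=config.filters,
            reduce_cap=config.reduce_cap,
            input_size=config.patch_size,
        )
    if config.arch == "default":
        return default_fabnet_spec(head_classes=head_classes)
    raise PipelineError(f"unknown architecture {config.arch!r}")
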