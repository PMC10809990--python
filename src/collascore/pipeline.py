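"""End-to-end pipeline: simulate -> preprocess -> train -> calibrate ->
predict -> evaluate, reproducible from one master seed.

The master seed fans out to per-stage seeds through a counter-based
``numpy.random.SeedSequence`` derivation, so stages are independently
reproducible.  All artifacts (manifests, logs, checkpoints, metric reports)
are written under one output directory.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .evaluate import (
    ThresholdCalibration,
    apply_threshold,
    average_distributions,
    calibrate_threshold,
    compute_metrics,
    quantitative_score,
)
from .network import BackboneConfig, SiameseCollateralNet, save_checkpoint
from .phantom import PhantomSpec, generate_dataset
from .training import TrainingConfig, AugmentationParams, train_model, _prepare_input

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "predict_all", "reduced_backbone"]

ABLATIONS = ("none", "no-siamese", "multiclass-only", "no-warmup")


def stage_seed(master_seed: int, stage: int) -> int:
    """Counter-based per-stage seed derived from the master seed."""
    return int(np.random.SeedSequence([master_seed, stage]).generate_state(1)[0] % (2**31 - 1))


def reduced_backbone(n_features: int = 8) -> BackboneConfig:
    """CPU-sized backbone used for phantom-scale experiments."""
    return BackboneConfig(n_features=n_features, blocks=(0, 2), full_res_stem=False)


@dataclass
class RunConfig:
    """Everything one end-to-end phantom run needs; YAML round-trippable."""

    seed: int = 0
    n_per_class_train: int = 50
    n_per_class_test: int = 20
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    backbone: BackboneConfig = field(default_factory=reduced_backbone)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    target_sensitivity: float = 0.81
    ablation: str = "none"
    ensemble: bool = False

    def __post_init__(self) -> None:
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}")

    # ------------------------------------------------------------- yaml round trip
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["phantom"] = PhantomSpec(**{**raw["phantom"], "shape": tuple(raw["phantom"]["shape"])})
        raw["backbone"] = BackboneConfig(
            **{**raw["backbone"], "blocks": tuple(raw["backbone"]["blocks"])}
        )
        tr = dict(raw["training"])
        tr["aug"] = AugmentationParams(**tr["aug"])
        tr["seeds"] = tuple(tr["seeds"])
        raw["training"] = TrainingConfig(**tr)
        return cls(**raw)

    def resolve_ablation(self) -> "RunConfig":
        """Apply the ablation switch to the training configuration."""
        cfg = self
        tr = cfg.training
        if cfg.ablation == "no-siamese":
            tr = dataclasses.replace(tr, whole_brain=True)
        elif cfg.ablation == "multiclass-only":
            tr = dataclasses.replace(tr, alpha=1.0)
        elif cfg.ablation == "no-warmup":
            tr = dataclasses.replace(tr, scheduler="cosine_decay")
        return dataclasses.replace(cfg, training=tr)


def predict_all(models: list[SiameseCollateralNet], samples, config: TrainingConfig):
    """Ensemble score distributions for a list of samples."""
    dists = []
    for s in samples:
        x = _prepare_input(s, config)
        dists.append(average_distributions([m.predict(x) for m in models]))
    return dists


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages; returns a summary dict (also written as JSON)."""
    os.makedirs(outdir, exist_ok=True)
    config = config.resolve_ablation()
    log_lines = []

    def log(stage, msg):
        line = f"[{stage}] {msg}"
        log_lines.append(line)

    # stage 0: simulate
    s_sim = stage_seed(config.seed, 0)
    log("simulate", f"seed={s_sim}")
    train_samples, train_manifest = generate_dataset(
        config.n_per_class_train, seed=s_sim, spec=config.phantom
    )
    test_samples, test_manifest = generate_dataset(
        config.n_per_class_test, seed=stage_seed(config.seed, 1), spec=config.phantom
    )
    train_manifest.to_csv(os.path.join(outdir, "train_manifest.csv"), index=False)
    test_manifest.to_csv(os.path.join(outdir, "test_manifest.csv"), index=False)

    # stage 1: train (single model or seed ensemble)
    s_train = stage_seed(config.seed, 2)
    log("train", f"seed={s_train} ablation={config.ablation}")
    seeds = config.training.seeds if config.ensemble else (0,)
    models = []
    for k, seed_k in enumerate(seeds):
        model, tlog = train_model(
            train_samples,
            config.training,
            seed=s_train + seed_k,
            val_samples=test_samples if k == 0 else None,
            backbone=config.backbone,
        )
        tlog.to_csv(os.path.join(outdir, f"training_log_{k}.csv"), index=False)
        save_checkpoint(
            model,
            os.path.join(outdir, f"model_{k}.npz"),
            metadata=getattr(model, "train_metadata", {}),
        )
        models.append(model)

    # stage 2: calibrate threshold on the training set predictions
    log("calibrate", f"target_sensitivity={config.target_sensitivity}")
    train_dists = predict_all(models, train_samples, config.training)
    train_labels = [s.score for s in train_samples]
    calib = calibrate_threshold(
        train_dists, train_labels, config.target_sensitivity, calibration_set_id="train"
    )

    # stage 3: predict + evaluate on the held-out set
    log("evaluate", f"theta={calib.theta:.4f}")
    test_dists = predict_all(models, test_samples, config.training)
    test_labels = [s.score for s in test_samples]
    rows = []
    for s, d in zip(test_samples, test_dists):
        score, dich = apply_threshold(d, calib.theta)
        rows.append(
            {
                "score_pred": score,
                "dichotomized_pred": dich,
                "p0": d[0],
                "p1": d[1],
                "p2": d[2],
                "p3": d[3],
                "p23": d.p23,
                "quantitative_score": quantitative_score(d),
                "score_ref": s.score,
            }
        )
    pred_df = pd.DataFrame(rows)
    pred_df.to_csv(os.path.join(outdir, "predictions.csv"), index=False)
    report = compute_metrics(
        pred_df["score_pred"], pred_df["score_ref"], pred_df["p23"]
    )
    report.to_json(os.path.join(outdir, "metrics.json"))
    report.roc_points.to_csv(os.path.join(outdir, "roc.csv"), index=False)

    summary = {
        "theta": calib.theta,
        "target_sensitivity": calib.target_sensitivity,
        "multiclass_accuracy": report.multiclass_accuracy,
        "dichotomized_accuracy": report.dichotomized_accuracy,
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "auc": report.auc,
        "ablation": config.ablation,
        "seed": config.seed,
        "log": log_lines,
    }
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
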