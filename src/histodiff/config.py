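"""Run configuration and the staged end-to-end pipeline.

A run is described by a YAML file with nested blocks (schedule,
denoiser, sampler, fusion, optimizer, detector, data, paths) plus a
seed. Defaults are the reference training recipe — AdamW at base
learning rate 1e-4 with 5000 warmup steps and 2e5 training steps,
128×128 patches, batch 16, 1000-step linear schedule — and a ``profile:
toy`` switch rescales everything to sizes a single CPU handles in
minutes (16×16 patches, T=50, small U-Net, 200 synthetic patches).
Unknown keys and type mismatches are rejected with the offending key
named. Every stage logs its seed and the config hash, and all file
outputs are written atomically (temp + rename).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diffusion import DEFAULT_BETA_END, DEFAULT_BETA_START, linear_schedule
from .denoiser import DenoiserConfig, build_denoiser, save_checkpoint
from .fusion import (DetectorTrainSettings, FusionConfig, build_detector,
                     evaluate_detector, run_fusion_ablation, train_detector)
from .metrics import binomial_ci, pr_auc, segmentation_report
from .sampler import SamplerConfig, TrainSettings, segment_batch, train_segmenter
from .synthetic import FixtureSpec, generate_detection_dataset, generate_segmentation_dataset

logger = logging.getLogger("histodiff")

__all__ = ["RunConfig", "load_config", "run_pipeline", "atomic_write_text"]


@dataclass
class ScheduleBlock:
    T: int = 1000
    beta_start: float = DEFAULT_BETA_START
    beta_end: float = DEFAULT_BETA_END
    family: str = "linear"


@dataclass
class DenoiserBlock:
    base_channels: int = 64
    depth: int = 3
    attention_levels: list = None
    time_embed_dim: int = 64


@dataclass
class SamplerBlock:
    inference_steps: int = None
    variance_mode: str = "fixed_beta"
    noise_modality_rule: str = "final"


@dataclass
class FusionBlock:
    mode: str = "transformer_decoder"
    modalities: list = field(default_factory=lambda: ["image", "mask", "noise"])
    embed_dim: int = 32
    heads: int = 4
    layers: int = 1
    query_modality: str = "image"


@dataclass
class OptimizerBlock:
    lr: float = 1e-4
    warmup_steps: int = 5000
    train_steps: int = 200_000
    batch_size: int = 16
    weight_decay: float = 0.01


@dataclass
class DetectorBlock:
    lr: float = 1e-3
    epochs: int = 30
    batch_size: int = 32
    backbone: str = "small"
    stages: int = 3


@dataclass
class DataBlock:
    image_size: int = 128
    k_classes: int = 5
    n_patches: int = 1000
    n_detection: int = 400
    cancer_fraction: float = 0.5


@dataclass
class PathsBlock:
    out_dir: str = "runs/default"


# toy profile: CPU-minutes scale. T is cut to 50 and beta_end raised so
# that alpha_bar(T) stays ~0 (the reverse chain must still start from
# pure noise); the tiny U-Net tolerates a larger learning rate.
_TOY_OVERRIDES = {
    "schedule": {"T": 50, "beta_end": 0.3},
    "denoiser": {"base_channels": 16, "depth": 2},
    "sampler": {"inference_steps": 25, "variance_mode": "zero"},
    "optimizer": {"lr": 2e-3, "warmup_steps": 100, "train_steps": 3200, "batch_size": 16},
    "detector": {"epochs": 25},
    "data": {"image_size": 16, "k_classes": 3, "n_patches": 200, "n_detection": 400},
}


@dataclass
class RunConfig:
    schedule: ScheduleBlock = field(default_factory=ScheduleBlock)
    denoiser: DenoiserBlock = field(default_factory=DenoiserBlock)
    sampler: SamplerBlock = field(default_factory=SamplerBlock)
    fusion: FusionBlock = field(default_factory=FusionBlock)
    optimizer: OptimizerBlock = field(default_factory=OptimizerBlock)
    detector: DetectorBlock = field(default_factory=DetectorBlock)
    data: DataBlock = field(default_factory=DataBlock)
    paths: PathsBlock = field(default_factory=PathsBlock)
    profile: str = "reference"
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _apply(block, overrides: dict, context: str) -> None:
    fields = {f.name: f for f in dataclasses.fields(block)}
    for key, value in overrides.items():
        if key not in fields:
            raise ValueError(f"unknown config key {context}.{key}")
        current = getattr(block, key)
        if current is not None and value is not None:
            want = type(current)
            if want in (int, float) and isinstance(value, bool):
                raise ValueError(f"type mismatch at {context}.{key}: boolean given")
            if want is float and isinstance(value, int):
                value = float(value)
            elif want is int and isinstance(value, float) and value == int(value):
                value = int(value)
            elif not isinstance(value, want):
                raise ValueError(
                    f"type mismatch at {context}.{key}: expected {want.__name__}, "
                    f"got {type(value).__name__}")
        setattr(block, key, value)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Parse and validate a YAML run configuration.

    An empty (or absent) file yields pure defaults. ``profile: toy``
    applies the toy-scale block before any explicit keys from the file.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            raw = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ValueError(f"malformed config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    if overrides:
        for key, value in overrides.items():
            if isinstance(value, dict) and isinstance(raw.get(key), dict):
                raw[key].update(value)
            else:
                raw[key] = value
    cfg = RunConfig()
    profile = raw.pop("profile", "reference")
    if profile not in ("reference", "toy"):
        raise ValueError(f"unknown profile {profile!r} (expected 'reference' or 'toy')")
    cfg.profile = profile
    if profile == "toy":
        for block_name, block_over in _TOY_OVERRIDES.items():
            _apply(getattr(cfg, block_name), block_over, block_name)
    for key, value in raw.items():
        if key == "seed":
            if value is None:
                raise ValueError("seed must be an integer, got null")
            cfg.seed = int(value)
        elif hasattr(cfg, key) and dataclasses.is_dataclass(getattr(cfg, key)):
            if not isinstance(value, dict):
                raise ValueError(f"config block {key!r} must be a mapping")
            _apply(getattr(cfg, key), value, key)
        else:
            raise ValueError(f"unknown config key {key!r}")
    return cfg


def atomic_write_text(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _df_csv(df: pd.DataFrame) -> str:
    return df.to_csv(index=False, float_format="%.6f")


def run_pipeline(config: RunConfig, include_ablation: bool = False) -> dict:
    """Execute simulate → train-seg → segment → train-detect → evaluate.

    Returns a dict of artifact paths and headline metrics. Re-running
    with an identical config reproduces identical metric files.
    """
    out = Path(config.paths.out_dir)
    chash = config.config_hash()
    stage = "simulate"
    try:
        logger.info("pipeline start: seed=%d config=%s", config.seed, chash)
        d = config.data
        spec = FixtureSpec(size=d.image_size, K=d.k_classes, n=d.n_patches,
                           cancer_fraction=d.cancer_fraction, seed=config.seed)
        seg_data = generate_segmentation_dataset(spec)
        det_spec = dataclasses.replace(spec, n=d.n_detection, seed=config.seed + 1)
        det_data = generate_detection_dataset(det_spec)

        stage = "train-seg"
        schedule = linear_schedule(config.schedule.T, config.schedule.beta_start,
                                   config.schedule.beta_end)
        dcfg = DenoiserConfig(K=d.k_classes, base_channels=config.denoiser.base_channels,
                              depth=config.denoiser.depth,
                              attention_levels=config.denoiser.attention_levels,
                              time_embed_dim=config.denoiser.time_embed_dim,
                              image_size=d.image_size)
        handle = build_denoiser(dcfg, config.seed + 2)
        settings = TrainSettings(lr=config.optimizer.lr,
                                 warmup_steps=config.optimizer.warmup_steps,
                                 train_steps=config.optimizer.train_steps,
                                 batch_size=config.optimizer.batch_size,
                                 weight_decay=config.optimizer.weight_decay)
        handle, loss_trace = train_segmenter(seg_data.train, handle, schedule,
                                             settings, rng_seed=config.seed + 3)
        out.mkdir(parents=True, exist_ok=True)
        save_checkpoint(out / "segmenter.npz", handle, schedule)

        stage = "segment"
        scfg = SamplerConfig(schedule=schedule,
                             inference_steps=config.sampler.inference_steps,
                             variance_mode=config.sampler.variance_mode,
                             noise_modality_rule=config.sampler.noise_modality_rule)
        test_imgs = [p.image for p in seg_data.test]
        seg_results = segment_batch(handle, test_imgs, scfg, rng_seed=config.seed + 4)
        report = segmentation_report([r.mask for r in seg_results],
                                     [p.mask for p in seg_data.test], d.k_classes)
        seg_df = pd.DataFrame(report["per_class"])
        atomic_write_text(out / "segmentation_metrics.csv", _df_csv(seg_df))

        stage = "train-detect"
        n_det = len(det_data)
        n_tr = int(round(0.7 * n_det))
        det_train, det_test = det_data[:n_tr], det_data[n_tr:]
        fcfg = FusionConfig(mode=config.fusion.mode,
                            modalities=tuple(config.fusion.modalities),
                            embed_dim=config.fusion.embed_dim, heads=config.fusion.heads,
                            layers=config.fusion.layers,
                            query_modality=config.fusion.query_modality)
        detector = build_detector(fcfg, config.seed + 5,
                                  backbone=config.detector.backbone,
                                  stages=config.detector.stages)
        segs_train = segment_batch(handle, [p.image for p, _ in det_train], scfg,
                                   rng_seed=config.seed + 6)
        segs_test = segment_batch(handle, [p.image for p, _ in det_test], scfg,
                                  rng_seed=config.seed + 7)
        dset = DetectorTrainSettings(lr=config.detector.lr, epochs=config.detector.epochs,
                                     batch_size=config.detector.batch_size)
        detector, acc_trace = train_detector(det_train, segs_train, detector,
                                             dset, rng_seed=config.seed + 8)

        stage = "detect"
        scores, pred, acc = evaluate_detector(detector, det_test, segs_test)
        y = np.array([1 if lab == "cancer" else 0 for _, lab in det_test])
        lo, hi = binomial_ci(acc, len(y))
        auc = pr_auc(scores, y) if y.any() else float("nan")
        det_df = pd.DataFrame([{"accuracy": acc, "ci_lo": lo, "ci_hi": hi,
                                "pr_auc": auc, "n": len(y)}])
        atomic_write_text(out / "detection_metrics.csv", _df_csv(det_df))
        fg = [r["iou"] for r in report["per_class"][1:]]
        fg_iou = float(np.mean(fg)) if fg else 1.0
        ablation_rows = None
        if include_ablation:
            stage = "ablate-fusion"
            ablation_rows = run_fusion_ablation(
                det_train, segs_train, det_test, segs_test,
                DetectorTrainSettings(lr=config.detector.lr,
                                      epochs=config.detector.epochs,
                                      batch_size=config.detector.batch_size),
                rng_seed=config.seed + 9, embed_dim=config.fusion.embed_dim,
                backbone=config.detector.backbone, stages=config.detector.stages)
            atomic_write_text(out / "fusion_ablation.csv",
                              _df_csv(pd.DataFrame(ablation_rows)))
            stage = "detect"
        meta = {"seed": config.seed, "config_hash": chash,
                "final_train_loss": loss_trace[-1], "final_train_acc": acc_trace[-1]}
        atomic_write_text(out / "run.json", json.dumps(meta, indent=2, sort_keys=True))
        logger.info("pipeline done: seg fg IoU %.3f, det accuracy %.3f", fg_iou, acc)
        return {"out_dir": str(out), "mean_iou": report["mean_iou"],
                "foreground_iou": fg_iou, "detection_accuracy": acc,
                "detection_pr_auc": float(auc), "detection_ci": [lo, hi],
                "n_detection_test": int(len(y)), "config_hash": chash,
                "ablation": ablation_rows}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
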