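"""End-to-end orchestration: synth -> preprocess -> train -> evaluate ->
explain, with one global seed, per-stage derived seeds, and a
reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .exceptions import ConfigError
from .evaluation import confusion, report_from_confusion, roc_auc
from .interpretability import grad_cam
from .model import CBGMModel, ModelConfig, load_weights, save_weights
from .preprocessing import DenoiseConfig, RPeakConfig, denoise, detect_r_peaks, segment_pulses
from .signal_io import CLASSES, SegmentDataset, read_segments, write_segments
from .synthetic_ecg import SynthConfig, make_classification_fixture
from .training import TrainConfig, split, train

logger = logging.getLogger("cbgm")

__all__ = ["PipelineConfig", "run_pipeline", "derive_seed"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Nested stage configs plus the global seed and output directory."""

    seed: int = 0
    out_dir: str = "cbgm_run"
    n_per_class: int = 200
    stages: dict = field(
        default_factory=lambda: {
            "synth": True, "train": True, "evaluate": True, "explain": True,
        }
    )
    synth: SynthConfig = field(default_factory=SynthConfig)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    rpeak: RPeakConfig = field(default_factory=RPeakConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    checkpoint: str = ""

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("seed", "out_dir", "n_per_class", "stages", "checkpoint"):
            if key in raw:
                kwargs[key] = raw[key]
        for key, sub_cls in (
            ("synth", SynthConfig), ("denoise", DenoiseConfig),
            ("rpeak", RPeakConfig), ("model", ModelConfig),
            ("train", TrainConfig),
        ):
            if key in raw:
                kwargs[key] = sub_cls(**raw[key])
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "seed": self.seed, "n_per_class": self.n_per_class,
                "stages": self.stages,
                "synth": vars(self.synth) | {"class_sequence": None},
                "denoise": vars(self.denoise),
                "rpeak": vars(self.rpeak),
                "model": self.model.to_dict(),
                "train": {k: v for k, v in vars(self.train).items() if k != "grid"},
            },
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages and write a run manifest.

    Returns the manifest dict.  Any stage failure aborts with the stage
    name prefixed to the error.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    artifacts: dict = {}
    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "versions": {"cbgm": __version__, "numpy": np.__version__},
        "artifacts": artifacts,
    }
    stage = "synth"
    try:
        seg_path = os.path.join(cfg.out_dir, "segments.csv")
        if cfg.stages.get("synth", True):
            synth_cfg = SynthConfig(
                **{**vars(cfg.synth), "seed": derive_seed(cfg.seed, "synth")}
            )
            dataset, _ = make_classification_fixture(cfg.n_per_class, synth_cfg)
            write_segments(dataset, seg_path)
            artifacts["segments"] = seg_path
        else:
            dataset = read_segments(seg_path)
            artifacts["segments"] = seg_path

        stage = "train"
        ckpt = cfg.checkpoint or os.path.join(cfg.out_dir, "model.npz")
        tr, te = split(dataset, cfg.train.split_ratio, derive_seed(cfg.seed, "split"))
        if cfg.stages.get("train", True):
            model = CBGMModel(cfg.model, seed=derive_seed(cfg.seed, "model"))
            tcfg = TrainConfig(
                **{**vars(cfg.train), "seed": derive_seed(cfg.seed, "train")}
            )
            _, hist = train(model, tr, te, tcfg)
            save_weights(model, ckpt)
            artifacts["checkpoint"] = ckpt
            artifacts["history"] = os.path.join(cfg.out_dir, "history.json")
            with open(artifacts["history"], "w") as fh:
                json.dump(vars(hist), fh, indent=1)
        else:
            if not os.path.exists(ckpt):
                raise ConfigError(
                    "training disabled but no checkpoint provided "
                    f"(missing dependency: {ckpt})"
                )
            model = load_weights(ckpt)
            artifacts["checkpoint"] = ckpt

        stage = "evaluate"
        if cfg.stages.get("evaluate", True):
            Xte, yte = te.to_arrays()
            probs = model.predict_proba(Xte)
            pred = probs.argmax(axis=1)
            cm = confusion([CLASSES[i] for i in yte], [CLASSES[i] for i in pred])
            report = report_from_confusion(cm)
            _, macro_auc = roc_auc([CLASSES[i] for i in yte], probs)
            metrics_path = os.path.join(cfg.out_dir, "metrics.json")
            with open(metrics_path, "w") as fh:
                json.dump(
                    {
                        "micro_accuracy": report.micro_accuracy,
                        "macro": report.macro,
                        "per_class": {
                            c: {k: v for k, v in report.per_class[c].items()}
                            for c in CLASSES
                        },
                        "macro_auc": macro_auc,
                        "confusion": cm.counts.tolist(),
                    },
                    fh, indent=1,
                )
            artifacts["metrics"] = metrics_path

        stage = "explain"
        if cfg.stages.get("explain", True):
            Xte, yte = te.to_arrays()
            idx = int(np.flatnonzero(yte == CLASSES.index("V"))[0]) if (
                yte == CLASSES.index("V")
            ).any() else 0
            sal = grad_cam(model, Xte[idx], CLASSES[yte[idx]])
            sal_path = os.path.join(cfg.out_dir, "saliency.csv")
            np.savetxt(sal_path, sal.values, header=f"gradcam_{sal.target_class}")
            artifacts["saliency"] = sal_path
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    manifest_path = os.path.join(cfg.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    artifacts["manifest"] = manifest_path
    return manifest
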