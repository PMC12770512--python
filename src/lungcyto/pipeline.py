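"""End-to-end pipeline orchestration.

Stages run in a fixed order — generate, preprocess, features, lighten,
split, train, evaluate — each reading the previous stage's directory
and manifest and writing its own, so any prefix of the chain can be
run and re-run reproducibly.  Filenames keep the source name with a
stage suffix (``_denoised`` after preprocessing) and the lightened
images go to a ``final2`` directory, mirroring the lab workflow the
pipeline automates.  A JSON run report records per-stage file counts,
checksums and metrics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import augment as aug
from . import features as feat
from . import metrics as ev
from . import preprocess as prep
from . import splits as sp
from . import synth
from ._util import load_gray, save_gray
from .errors import DependencyError
from .nn import build_hybrid, desk_config, predict, train_model

STAGES = ("generate", "preprocess", "features", "lighten", "split",
          "train", "evaluate")


@dataclass
class PipelineConfig:
    """Nested stage configuration with one global seed.

    The global seed deterministically derives every stage seed, so a
    run is a pure function of its configuration.
    """

    out_dir: str = "runs/pipeline"
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    synth: synth.SynthConfig | None = None
    clahe: prep.ClaheConfig | None = None
    feature: feat.FeatureConfig | None = None
    split: sp.SplitConfig | None = None
    augment_cfg: aug.AugmentConfig | None = None
    model: "object | None" = None
    image_size: tuple[int, int] = (64, 64)
    per_class_count: int = 10
    use_augmentation: bool = False

    def __post_init__(self):
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise DependencyError(f"unknown stages {bad}")
        if self.synth is None:
            self.synth = synth.SynthConfig(
                per_class_count=self.per_class_count,
                image_size=self.image_size, seed=self.seed)
        if self.clahe is None:
            self.clahe = prep.ClaheConfig()
        if self.feature is None:
            self.feature = feat.FeatureConfig()
        if self.split is None:
            self.split = sp.SplitConfig(
                per_class_cap=self.per_class_count,
                train_per_class=max(int(round(self.per_class_count * 0.75)), 1),
                seed=self.seed)
        if self.augment_cfg is None:
            self.augment_cfg = aug.AugmentConfig(seed=self.seed)
        if self.model is None:
            self.model = desk_config(seed=self.seed, epochs=15)


def _dir_checksum(paths) -> str:
    h = hashlib.sha256()
    for p in sorted(str(p) for p in paths):
        h.update(Path(p).read_bytes())
    return h.hexdigest()


def _stage_dir(cfg: PipelineConfig, stage: str) -> Path:
    return Path(cfg.out_dir) / stage


def _require(cfg: PipelineConfig, stage: str, needed: str) -> Path:
    d = _stage_dir(cfg, needed)
    if not (d / "manifest.csv").exists():
        raise DependencyError(
            f"stage {stage!r} requires outputs of {needed!r}; run it first")
    return d


def _transform_images(cfg, stage, upstream, fn, suffix=""):
    """Apply ``fn(image) -> image`` to every manifest row of the
    upstream stage, writing renamed copies and a new manifest."""
    src_dir = _require(cfg, stage, upstream)
    manifest = sp.read_manifest(src_dir / "manifest.csv")
    out_dir = _stage_dir(cfg, stage)
    rows = []
    for _, row in manifest.iterrows():
        img = fn(load_gray(row["path"]))
        src = Path(row["path"])
        name = src.stem + suffix + src.name[len(src.stem):]
        dest = out_dir / src.parent.name / name
        dest.parent.mkdir(parents=True, exist_ok=True)
        save_gray(img, dest)
        rows.append({**row, "path": str(dest)})
    out = pd.DataFrame(rows)
    sp.write_manifest(out, out_dir / "manifest.csv")
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stage chain; returns the run report.

    Each stage is skippable (leave it out of ``cfg.stages``) but the
    chain must be prefix-closed: a stage whose upstream outputs are
    missing raises :class:`DependencyError` naming the stage.
    """
    report: dict = {"seed": cfg.seed, "stages": {}}
    out_root = Path(cfg.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)

    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        if stage == "generate":
            d = _stage_dir(cfg, "generate")
            manifest = synth.generate_dataset(cfg.synth, d)
            report["stages"]["generate"] = {
                "files": int(len(manifest)),
                "checksum": _dir_checksum(manifest["path"]),
            }
        elif stage == "preprocess":
            manifest = _transform_images(
                cfg, "preprocess", "generate",
                lambda im: prep.preprocess_image(
                    im, target=cfg.synth.image_size, clahe=cfg.clahe),
                suffix="_denoised")
            report["stages"]["preprocess"] = {
                "files": int(len(manifest)),
                "checksum": _dir_checksum(manifest["path"]),
            }
        elif stage == "features":
            qms = []

            def _features(im):
                final, fg, dark, otsu = feat.extract_features(im, cfg.feature)
                qms.append(int(otsu.threshold))
                return final

            manifest = _transform_images(cfg, "features", "preprocess",
                                         _features)
            report["stages"]["features"] = {
                "files": int(len(manifest)),
                "checksum": _dir_checksum(manifest["path"]),
                "otsu_mean": float(np.mean(qms)),
                "otsu_min": int(np.min(qms)),
                "otsu_max": int(np.max(qms)),
            }
        elif stage == "lighten":
            src_dir = _require(cfg, "lighten", "features")
            manifest = sp.read_manifest(src_dir / "manifest.csv")
            out_dir = _stage_dir(cfg, "lighten") / "final2"
            rows = []
            for _, row in manifest.iterrows():
                img = feat.midtone_lighten(load_gray(row["path"]), cfg.feature)
                src = Path(row["path"])
                dest = out_dir / src.parent.name / src.name
                dest.parent.mkdir(parents=True, exist_ok=True)
                save_gray(img, dest)
                rows.append({**row, "path": str(dest)})
            manifest = pd.DataFrame(rows)
            sp.write_manifest(manifest, _stage_dir(cfg, "lighten") / "manifest.csv")
            report["stages"]["lighten"] = {
                "files": int(len(manifest)),
                "checksum": _dir_checksum(manifest["path"]),
            }
        elif stage == "split":
            src_dir = _require(cfg, "split", "lighten")
            manifest = sp.read_manifest(src_dir / "manifest.csv")
            sealed = sp.seal_classes(manifest, cfg.split)
            split = sp.holdout_split(sealed, cfg.split)
            d = _stage_dir(cfg, "split")
            d.mkdir(parents=True, exist_ok=True)
            sp.write_manifest(split, d / "manifest.csv")
            report["stages"]["split"] = {
                "files": int(len(split)),
                **sp.split_summary(split),
            }
        elif stage == "train":
            src_dir = _require(cfg, "train", "split")
            manifest = sp.read_manifest(src_dir / "manifest.csv")
            train_rows = manifest[manifest["split"] == "train"]
            images = [load_gray(p) for p in train_rows["path"]]
            model = build_hybrid(cfg.model)
            history = train_model(
                model, images, list(train_rows["label"]), cfg.model,
                augment_cfg=cfg.augment_cfg if cfg.use_augmentation else None)
            d = _stage_dir(cfg, "train")
            d.mkdir(parents=True, exist_ok=True)
            history.to_frame().to_csv(d / "history.csv", index=False)
            np.savez(d / "weights.npz", *model.get_weights())
            report["stages"]["train"] = {
                "epochs": len(history.train_loss),
                "final_train_accuracy": history.train_accuracy[-1],
                "best_train_accuracy": max(history.train_accuracy),
            }
            report["_model"] = model
        elif stage == "evaluate":
            src_dir = _require(cfg, "evaluate", "split")
            manifest = sp.read_manifest(src_dir / "manifest.csv")
            model = report.pop("_model", None)
            if model is None:
                train_dir = _stage_dir(cfg, "train")
                if not (train_dir / "weights.npz").exists():
                    raise DependencyError(
                        "stage 'evaluate' requires a trained model; run "
                        "'train' first")
                model = build_hybrid(cfg.model)
                with np.load(train_dir / "weights.npz") as z:
                    model.set_weights([z[k] for k in z.files])
            test_rows = manifest[manifest["split"] == "test"]
            images = [load_gray(p) for p in test_rows["path"]]
            _, pred = predict(model, images)
            cm = ev.confusion_from_predictions(
                list(test_rows["label"]), pred, synth.CLASS_NAMES)
            m = ev.metrics_from_confusion(cm)
            d = _stage_dir(cfg, "evaluate")
            d.mkdir(parents=True, exist_ok=True)
            cm.to_frame().to_csv(d / "confusion.csv")
            result = {"accuracy": m.accuracy,
                      "macro_f1": m.macro_f1,
                      "per_class": m.per_class}
            (d / "metrics.json").write_text(json.dumps(result, indent=2))
            report["stages"]["evaluate"] = {"files": int(len(test_rows)),
                                            **result}
    report.pop("_model", None)
    (out_root / "report.json").write_text(json.dumps(report, indent=2))
    return report
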