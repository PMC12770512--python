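"""Dataset manifest handling: class sealing, stratified hold-out
split, and stratified k-fold partitioning.

A manifest is a pandas DataFrame with columns ``path`` (unique),
``label``, ``split`` (train/test or empty) and ``fold`` (nullable
integer).  All sampling is uniform without replacement from a single
seeded generator, and every operation sorts rows by path first so the
outcome does not depend on the incoming row order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import round_half_away
from .errors import ConfigurationError, DataError, InsufficientDataError

MANIFEST_COLUMNS = ["path", "label", "split", "fold"]

#: Per-class hold-out counts of the published workflow (described
#: there as a 75:25 split of the 1500-image per-class cap; the printed
#: counts are 1050 train / 450 test per class).
PUBLISHED_TRAIN_PER_CLASS = 1050

#: Per-class cap used for cross-validation on the full balanced set
#: (4650 images, 1550 per class, 310 per class per fold at k=5).
CV_PER_CLASS_CAP = 1550


@dataclass(frozen=True)
class SplitConfig:
    """Sealing/splitting parameters.

    train_per_class
        Optional explicit per-class training count; when set it takes
        precedence over ``train_fraction`` (used to reproduce the
        published 1050/450 per-class split exactly).
    """

    per_class_cap: int = 1500
    train_fraction: float = 0.75
    k: int = 5
    seed: int = 0
    train_per_class: int | None = None

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ConfigurationError("train_fraction must be in (0, 1)")
        if self.k < 2:
            raise ConfigurationError("k must be >= 2")
        if self.per_class_cap < 1:
            raise ConfigurationError("per_class_cap must be >= 1")


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("path", "label") if c not in manifest.columns]
    if missing:
        raise DataError(f"manifest missing columns {missing}")
    if manifest["path"].duplicated().any():
        dup = manifest.loc[manifest["path"].duplicated(), "path"].iloc[0]
        raise DataError(f"duplicate manifest path {dup!r}")
    out = manifest.copy()
    if "split" not in out.columns:
        out["split"] = ""
    if "fold" not in out.columns:
        out["fold"] = pd.NA
    out["split"] = out["split"].fillna("")
    out["fold"] = out["fold"].astype("Int64")
    return out[MANIFEST_COLUMNS]


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"path": str, "label": str, "split": str})
    return validate_manifest(df)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    validate_manifest(manifest).to_csv(path, index=False)


def _sorted_class_paths(manifest: pd.DataFrame, label: str) -> pd.DataFrame:
    return manifest[manifest["label"] == label].sort_values("path")


def seal_classes(manifest: pd.DataFrame,
                 cfg: SplitConfig | None = None) -> pd.DataFrame:
    """Subsample every class down to exactly ``per_class_cap`` rows.

    Uniform, seeded, without replacement; raises
    :class:`InsufficientDataError` naming the first class that falls
    short of the cap.
    """
    manifest = validate_manifest(manifest)
    cfg = cfg or SplitConfig()
    rng = np.random.default_rng(cfg.seed)
    parts = []
    for label in sorted(manifest["label"].unique()):
        rows = _sorted_class_paths(manifest, label)
        if len(rows) < cfg.per_class_cap:
            raise InsufficientDataError(
                f"class {label!r} has {len(rows)} rows, below the "
                f"cap of {cfg.per_class_cap}")
        idx = rng.choice(len(rows), size=cfg.per_class_cap, replace=False)
        parts.append(rows.iloc[np.sort(idx)])
    return pd.concat(parts, ignore_index=True)


def holdout_split(manifest: pd.DataFrame,
                  cfg: SplitConfig | None = None) -> pd.DataFrame:
    """Stratified train/test hold-out assignment.

    Per class, ``round(n * train_fraction)`` rows (or the explicit
    ``train_per_class`` count) are marked ``train`` and the rest
    ``test`` after a seeded shuffle.
    """
    manifest = validate_manifest(manifest)
    cfg = cfg or SplitConfig()
    rng = np.random.default_rng(cfg.seed + 1)
    parts = []
    for label in sorted(manifest["label"].unique()):
        rows = _sorted_class_paths(manifest, label).reset_index(drop=True)
        n = len(rows)
        if cfg.train_per_class is not None:
            n_train = cfg.train_per_class
        else:
            n_train = int(round_half_away(n * cfg.train_fraction))
        if not 0 < n_train < n:
            raise ConfigurationError(
                f"class {label!r}: train count {n_train} of {n} leaves an "
                "empty train or test set")
        order = rng.permutation(n)
        rows = rows.iloc[order].reset_index(drop=True)
        rows.loc[: n_train - 1, "split"] = "train"
        rows.loc[n_train:, "split"] = "test"
        parts.append(rows)
    return pd.concat(parts, ignore_index=True).sort_values(
        "path", ignore_index=True)


def stratified_kfold(manifest: pd.DataFrame,
                     cfg: SplitConfig | None = None) -> pd.DataFrame:
    """Assign a fold index to every row, stratified by class.

    Per class the rows are shuffled (seeded) and dealt round-robin to
    the k folds, so per-class fold sizes differ by at most one and a
    balanced manifest yields exactly equal folds.
    """
    manifest = validate_manifest(manifest)
    cfg = cfg or SplitConfig()
    counts = manifest["label"].value_counts()
    if cfg.k > counts.min():
        raise ConfigurationError(
            f"k={cfg.k} exceeds the smallest class count {counts.min()}")
    rng = np.random.default_rng(cfg.seed + 2)
    parts = []
    for label in sorted(manifest["label"].unique()):
        rows = _sorted_class_paths(manifest, label).reset_index(drop=True)
        order = rng.permutation(len(rows))
        rows = rows.iloc[order].reset_index(drop=True)
        rows["fold"] = pd.array(np.arange(len(rows)) % cfg.k, dtype="Int64")
        parts.append(rows)
    return pd.concat(parts, ignore_index=True).sort_values(
        "path", ignore_index=True)


def split_summary(manifest: pd.DataFrame) -> dict:
    """Per-split and per-fold row counts, for run reports."""
    manifest = validate_manifest(manifest)
    out: dict = {"total": int(len(manifest))}
    if (manifest["split"] != "").any():
        out["split_counts"] = manifest["split"].value_counts().to_dict()
        out["split_by_class"] = {
            s: g["label"].value_counts().to_dict()
            for s, g in manifest[manifest["split"] != ""].groupby("split")
        }
    if manifest["fold"].notna().any():
        folds = manifest[manifest["fold"].notna()]
        out["fold_counts"] = {int(f): int(c) for f, c
                              in folds["fold"].value_counts().items()}
    return out
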