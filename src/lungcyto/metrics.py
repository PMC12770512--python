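"""Confusion-matrix metrics, cross-validation summaries and
external-test arithmetic.

Per-class precision, recall and F1 are one-vs-rest quantities derived
from a K x K confusion matrix (rows = true class, columns =
predicted):

    Tp = diagonal entry, Fp = column sum - Tp, Fn = row sum - Tp,
    P = Tp / (Tp + Fp),  R = Tp / (Tp + Fn),  F1 = 2PR / (P + R),
    accuracy = trace / total.

Ratios with a zero denominator are reported as ``None`` (an explicit
undefined marker), never silently as 0.  Fold summaries use the
sample (n-1) standard deviation, SE = SD / sqrt(n), CoV = SD / mean
and a normal-quantile confidence interval (z = 1.96 by default); all
values are kept at full precision internally and rounded only for
presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, InputError, StatisticsError


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K integer counts; rows are true classes, columns predicted."""

    class_names: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if counts.shape != (k, k):
            raise InputError(f"counts shape {counts.shape} does not match "
                             f"{k} classes")
        if (counts < 0).any():
            raise InputError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_names),
                            columns=list(self.class_names))


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class one-vs-rest metrics plus overall and macro averages.

    ``per_class`` maps class name to a dict with precision / recall /
    f1 / support; undefined ratios are ``None``.  Macro averages are
    ``None`` if any contributing value is undefined.
    """

    class_names: tuple[str, ...]
    per_class: dict
    accuracy: float
    macro_precision: float | None
    macro_recall: float | None
    macro_f1: float | None


@dataclass(frozen=True)
class FoldSummary:
    """Dispersion summary of per-fold metric values (percent scale)."""

    values: tuple[float, ...]
    mean: float
    sd: float
    se: float
    cov: float | None
    ci_low: float
    ci_high: float
    z: float = 1.96


@dataclass(frozen=True)
class ExternalTestRow:
    """One class of an external-collection test: counts and accuracy."""

    class_name: str
    n_tested: int
    n_correct: int

    def __post_init__(self):
        if self.n_tested <= 0:
            raise InputError(f"class {self.class_name!r}: n_tested must be "
                             "positive")
        if not 0 <= self.n_correct <= self.n_tested:
            raise InputError(f"class {self.class_name!r}: n_correct outside "
                             "[0, n_tested]")

    @property
    def n_misclassified(self) -> int:
        return self.n_tested - self.n_correct

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.n_correct / self.n_tested


def confusion_from_predictions(true_labels: Sequence[str],
                               predicted_labels: Sequence[str],
                               class_names: Sequence[str]) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a confusion matrix."""
    if len(true_labels) != len(predicted_labels):
        raise InputError("label lists have different lengths")
    index = {name: i for i, name in enumerate(class_names)}
    k = len(class_names)
    counts = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index:
            raise DataError(f"unknown true label {t!r}")
        if p not in index:
            raise DataError(f"unknown predicted label {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(tuple(class_names), counts)


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def metrics_from_confusion(cm: ConfusionMatrix) -> ClassMetrics:
    """Table of per-class precision/recall/F1 and overall accuracy."""
    total = cm.total
    if total == 0:
        raise InputError("empty confusion matrix")
    counts = cm.counts
    per_class = {}
    for i, name in enumerate(cm.class_names):
        tp = int(counts[i, i])
        fp = int(counts[:, i].sum() - tp)
        fn = int(counts[i, :].sum() - tp)
        p = _ratio(tp, tp + fp)
        r = _ratio(tp, tp + fn)
        if p is None or r is None or p + r == 0:
            f1 = None
        else:
            f1 = 2 * p * r / (p + r)
        per_class[name] = {"precision": p, "recall": r, "f1": f1,
                           "support": int(counts[i, :].sum())}

    def _macro(key: str) -> float | None:
        vals = [per_class[n][key] for n in cm.class_names]
        if any(v is None for v in vals):
            return None
        return float(np.mean(vals))

    return ClassMetrics(
        class_names=cm.class_names,
        per_class=per_class,
        accuracy=counts.trace() / total,
        macro_precision=_macro("precision"),
        macro_recall=_macro("recall"),
        macro_f1=_macro("f1"),
    )


def summarize_folds(values: Sequence[float], z: float = 1.96) -> FoldSummary:
    """Mean / sample SD / SE / CoV / normal CI over per-fold values."""
    vals = tuple(float(v) for v in values)
    n = len(vals)
    if n < 2:
        raise StatisticsError("need at least two fold values")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    se = sd / math.sqrt(n)
    cov = sd / mean if mean != 0 else None
    return FoldSummary(values=vals, mean=mean, sd=sd, se=se, cov=cov,
                       ci_low=mean - z * se, ci_high=mean + z * se, z=z)


def run_cross_validation(manifest: pd.DataFrame,
                         fit_predict: Callable[[pd.DataFrame, pd.DataFrame],
                                               Sequence[str]],
                         class_names: Sequence[str]) -> dict:
    """Evaluate a model builder across the manifest's fold assignment.

    ``fit_predict(train_rows, eval_rows)`` must train on the first
    frame and return predicted labels for the second, in row order.
    Returns per-fold :class:`ClassMetrics` plus :class:`FoldSummary`
    objects (percent scale) for accuracy and the macro averages.
    """
    if "fold" not in manifest.columns or manifest["fold"].isna().any():
        raise DataError("manifest rows are missing fold assignments")
    folds = sorted(int(f) for f in manifest["fold"].unique())
    per_fold = []
    for f in folds:
        eval_rows = manifest[manifest["fold"] == f].reset_index(drop=True)
        train_rows = manifest[manifest["fold"] != f].reset_index(drop=True)
        predicted = list(fit_predict(train_rows, eval_rows))
        cm = confusion_from_predictions(list(eval_rows["label"]), predicted,
                                        class_names)
        per_fold.append(metrics_from_confusion(cm))

    def _pct(vals):
        return [100.0 * v for v in vals]

    summaries = {}
    acc = _pct([m.accuracy for m in per_fold])
    summaries["accuracy"] = summarize_folds(acc)
    for key in ("macro_precision", "macro_recall", "macro_f1"):
        vals = [getattr(m, key) for m in per_fold]
        if all(v is not None for v in vals):
            summaries[key] = summarize_folds(_pct(vals))
    return {"per_fold": per_fold, "summaries": summaries}


def external_test_report(rows: Sequence[ExternalTestRow]) -> dict:
    """Per-class and overall accuracy of an external-collection test."""
    if not rows:
        raise InputError("no external-test rows")
    per_class = {r.class_name: {"n_tested": r.n_tested,
                                "n_correct": r.n_correct,
                                "n_misclassified": r.n_misclassified,
                                "accuracy_pct": r.accuracy_pct}
                 for r in rows}
    total = sum(r.n_tested for r in rows)
    correct = sum(r.n_correct for r in rows)
    return {"per_class": per_class,
            "overall_accuracy_pct": 100.0 * correct / total}


def format_fold_summary(summary: FoldSummary) -> dict:
    """Presentation rounding (2 dp for percents, 4 dp for SE)."""
    return {
        "mean": round(summary.mean, 2),
        "sd": round(summary.sd, 2),
        "se": round(summary.se, 4),
        "cov": round(summary.cov, 4) if summary.cov is not None else None,
        "ci": [round(summary.ci_low, 2), round(summary.ci_high, 2)],
    }
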