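"""Confusion-matrix metrics, fold summaries and external-test math."""

import math

import numpy as np
import pytest

from lungcyto.errors import DataError, InputError, StatisticsError
from lungcyto.metrics import (ClassMetrics, ConfusionMatrix, ExternalTestRow,
                              confusion_from_predictions,
                              external_test_report, format_fold_summary,
                              metrics_from_confusion, run_cross_validation,
                              summarize_folds)
from lungcyto.splits import SplitConfig, stratified_kfold
from conftest import make_manifest

CLASSES = ("adenocarcinoma", "neuroendocrine", "squamous")


def definition_oracle(counts: np.ndarray):
    """Per-definition Tp/Fp/Fn computation, one class at a time."""
    k = counts.shape[0]
    out = []
    for i in range(k):
        tp = counts[i, i]
        fp = counts[:, i].sum() - tp
        fn = counts[i, :].sum() - tp
        p = tp / (tp + fp) if tp + fp else None
        r = tp / (tp + fn) if tp + fn else None
        f1 = (2 * p * r / (p + r)) if p is not None and r is not None \
            and p + r > 0 else None
        out.append((p, r, f1))
    return out


def test_confusion_counting_and_errors():
    cm = confusion_from_predictions(
        ["a", "a", "b", "c", "c", "c"], ["a", "b", "b", "c", "c", "a"],
        ["a", "b", "c"])
    assert cm.counts.tolist() == [[1, 1, 0], [0, 1, 0], [1, 0, 2]]
    empty = confusion_from_predictions([], [], ["a", "b"])
    assert empty.counts.sum() == 0
    with pytest.raises(DataError, match="zz"):
        confusion_from_predictions(["zz"], ["a"], ["a"])


def test_confusion_matches_counting_oracle(rng):
    names = list("abc")
    true = rng.choice(names, 200)
    pred = rng.choice(names, 200)
    cm = confusion_from_predictions(list(true), list(pred), names)
    for i, t in enumerate(names):
        for j, p in enumerate(names):
            assert cm.counts[i, j] == sum(
                1 for a, b in zip(true, pred) if a == t and b == p)


def test_perfect_predictions_all_ones():
    cm = ConfusionMatrix(CLASSES, np.diag([3, 3, 3]))
    m = metrics_from_confusion(cm)
    assert m.accuracy == 1.0
    for c in CLASSES:
        assert m.per_class[c] == {"precision": 1.0, "recall": 1.0,
                                  "f1": 1.0, "support": 3}


def test_metrics_match_definition_oracle(rng):
    for _ in range(200):
        counts = rng.integers(0, 50, (3, 3))
        if counts.sum() == 0:
            continue
        m = metrics_from_confusion(ConfusionMatrix(CLASSES, counts))
        for name, (p, r, f1) in zip(CLASSES, definition_oracle(counts)):
            got = m.per_class[name]
            for key, want in (("precision", p), ("recall", r), ("f1", f1)):
                if want is None:
                    assert got[key] is None
                else:
                    assert got[key] == pytest.approx(want)
        assert m.accuracy == pytest.approx(counts.trace() / counts.sum())


def test_micro_accuracy_equals_direct_fraction(rng):
    names = list("abc")
    for _ in range(50):
        true = rng.choice(names, 60)
        pred = rng.choice(names, 60)
        cm = confusion_from_predictions(list(true), list(pred), names)
        m = metrics_from_confusion(cm)
        assert m.accuracy == pytest.approx(np.mean(true == pred))


def test_macro_recall_equals_accuracy_for_balanced_supports():
    counts = np.array([[8, 1, 1], [2, 7, 1], [0, 3, 7]])
    m = metrics_from_confusion(ConfusionMatrix(CLASSES, counts))
    assert m.macro_recall == pytest.approx(m.accuracy)


def test_undefined_ratios_marked_not_zeroed():
    counts = np.array([[5, 0, 0], [0, 0, 0], [0, 0, 0]])
    m = metrics_from_confusion(ConfusionMatrix(CLASSES, counts))
    assert m.per_class["neuroendocrine"]["recall"] is None
    assert m.macro_recall is None


def test_summarize_folds_dispersion_conventions():
    s = summarize_folds([99.47, 99.73, 99.80, 99.60, 99.87])
    assert s.mean == pytest.approx(99.694)
    assert s.sd == pytest.approx(0.160094, abs=1e-6)
    assert s.se == pytest.approx(0.071596, abs=1e-6)
    assert s.ci_low == pytest.approx(99.694 - 1.96 * s.se)
    assert s.ci_high == pytest.approx(99.694 + 1.96 * s.se)


def test_summarize_folds_degenerate_and_errors():
    s = summarize_folds([50.0] * 5)
    assert s.sd == 0 and s.se == 0
    assert s.ci_low == s.ci_high == 50.0
    with pytest.raises(StatisticsError):
        summarize_folds([1.0])


def test_summarize_folds_matches_two_pass_oracle(rng):
    vals = rng.uniform(90, 100, 5)
    s = summarize_folds(vals)
    mean = sum(vals) / len(vals)
    var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
    assert s.mean == pytest.approx(mean)
    assert s.sd == pytest.approx(math.sqrt(var))
    assert s.cov == pytest.approx(math.sqrt(var) / mean)


def test_summarize_folds_permutation_invariant(rng):
    vals = list(rng.uniform(0, 100, 6))
    a = summarize_folds(vals)
    b = summarize_folds(vals[::-1])
    assert (a.mean, a.sd, a.se, a.ci_low, a.ci_high) == \
        (b.mean, b.sd, b.se, b.ci_low, b.ci_high)


def test_cross_validation_with_mock_predictors():
    manifest = make_manifest({c: 10 for c in CLASSES})
    manifest = stratified_kfold(manifest, SplitConfig(k=5, seed=0))

    def memorizing(train_rows, eval_rows):
        return list(eval_rows["label"])

    out = run_cross_validation(manifest, memorizing, CLASSES)
    s = out["summaries"]["accuracy"]
    assert s.values == (100.0,) * 5
    assert s.sd == 0

    def constant(train_rows, eval_rows):
        return ["adenocarcinoma"] * len(eval_rows)

    out2 = run_cross_validation(manifest, constant, CLASSES)
    for m in out2["per_fold"]:
        assert m.accuracy == pytest.approx(1 / 3)


def test_cross_validation_requires_fold_assignment(balanced_manifest):
    with pytest.raises(DataError):
        run_cross_validation(balanced_manifest,
                             lambda a, b: list(b["label"]), CLASSES)


def test_external_test_rows():
    rows = [ExternalTestRow("adenocarcinoma", 100, 97),
            ExternalTestRow("neuroendocrine", 100, 100)]
    report = external_test_report(rows)
    assert report["per_class"]["adenocarcinoma"]["accuracy_pct"] == 97.0
    assert report["per_class"]["adenocarcinoma"]["n_misclassified"] == 3
    assert report["per_class"]["neuroendocrine"]["accuracy_pct"] == 100.0
    with pytest.raises(InputError):
        ExternalTestRow("x", 0, 0)


def test_presentation_rounding_is_display_only():
    s = summarize_folds([99.47, 99.73, 99.80, 99.60, 99.87])
    disp = format_fold_summary(s)
    assert disp["mean"] == 99.69 and disp["se"] == 0.0716
    # internal values keep full precision
    assert s.mean != disp["mean"]
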