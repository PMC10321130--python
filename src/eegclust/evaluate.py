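"""Confusion-matrix metrics, MSE, and the stratified K-fold benchmark.

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP) and accuracy =
(TP+TN)/total are reported as percentages; for balanced test sets accuracy
equals the mean of sensitivity and specificity, the identity every row of
the consolidated benchmark tables satisfies.  The benchmark shares one
seeded stratified fold partition across all classifiers so comparisons are
paired, and aggregates by averaging per-fold metrics (pooled-count
aggregation is available via a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classify import ClassifierSpec, build_classifier

#: Decimal places in emitted tables.
TABLE_PRECISION = 5


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with the seizure class as positive.

    Counts may be real-valued (rates per 100) for arithmetic checks; the
    metric formulas are homogeneous in the counts.
    """

    tp: float
    tn: float
    fp: float
    fn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> float:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsRow:
    """Sensitivity/specificity/accuracy in percent, plus MSE."""

    sensitivity: float
    specificity: float
    accuracy: float
    mse: float = float("nan")


def confusion_counts(y_true, y_pred, positive_label) -> ConfusionCounts:
    """Count TP/TN/FP/FN for a binary problem."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    labels = set(np.unique(y_true)) | set(np.unique(y_pred))
    if len(labels) > 2:
        raise ValueError(f"binary labels expected, got {sorted(map(str, labels))}")
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    return ConfusionCounts(
        tp=float(np.sum(pos_t & pos_p)),
        tn=float(np.sum(~pos_t & ~pos_p)),
        fp=float(np.sum(~pos_t & pos_p)),
        fn=float(np.sum(pos_t & ~pos_p)),
    )


def classification_metrics(c: ConfusionCounts) -> MetricsRow:
    """Sensitivity, specificity and accuracy (percent) from counts."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ZeroDivisionError("metrics undefined without both classes present")
    sens = 100.0 * c.tp / (c.tp + c.fn)
    spec = 100.0 * c.tn / (c.tn + c.fp)
    acc = 100.0 * (c.tp + c.tn) / c.total
    return MetricsRow(sens, spec, acc)


def mse(observed, target) -> float:
    """Mean squared difference between two equal-length series."""
    v = np.asarray(observed, dtype=float)
    w = np.asarray(target, dtype=float)
    if v.shape != w.shape:
        raise ValueError("series must have equal length")
    if v.size == 0:
        raise ValueError("series must be nonempty")
    return float(np.mean((v - w) ** 2))


@dataclass
class CVResult:
    """Per-fold and aggregate metrics for one classifier spec."""

    spec: ClassifierSpec
    fold_metrics: list[MetricsRow]
    aggregate: MetricsRow
    fold_assignment: np.ndarray  # test-fold index per instance


def run_kfold_benchmark(
    features: np.ndarray | pd.DataFrame,
    labels,
    classifier_specs: list[ClassifierSpec],
    positive_label,
    K: int = 10,
    seed: int = 0,
    pooled: bool = False,
) -> tuple[dict[str, CVResult], pd.DataFrame]:
    """Stratified K-fold benchmark over a roster of classifiers.

    One seeded fold partition is shared by every spec.  Per spec and fold
    the model is fit on the other K-1 folds and scored on the held-out
    fold; fold metrics are averaged (or counts pooled with
    ``pooled=True``).  Returns per-spec results plus a consolidated table
    with sensitivity/specificity/accuracy (percent) and MSE columns.
    """
    if isinstance(features, pd.DataFrame):
        feat_cols = [c for c in features.columns if c.startswith("f")]
        X = features[feat_cols].to_numpy(float)
    else:
        X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if K < 2:
        raise ValueError("K must be >= 2")
    _, class_counts = np.unique(y, return_counts=True)
    if K > class_counts.min():
        raise ValueError(f"K={K} exceeds the smallest class count {class_counts.min()}")

    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    fold_assignment = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(folds):
        fold_assignment[test_idx] = f

    y_bin = (y == positive_label).astype(float)
    results: dict[str, CVResult] = {}
    rows = []
    for spec in classifier_specs:
        fold_rows: list[MetricsRow] = []
        counts_sum = np.zeros(4)
        sq_errors: list[float] = []
        for train_idx, test_idx in folds:
            clf = build_classifier(spec)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(X[train_idx], y[train_idx])
                pred = np.asarray(clf.predict(X[test_idx]))
            c = confusion_counts(y[test_idx], pred, positive_label)
            m = classification_metrics(c)
            fold_err = mse((pred == positive_label).astype(float), y_bin[test_idx])
            fold_rows.append(MetricsRow(m.sensitivity, m.specificity, m.accuracy, fold_err))
            counts_sum += (c.tp, c.tn, c.fp, c.fn)
            sq_errors.append(fold_err)
        if pooled:
            pooled_counts = ConfusionCounts(*counts_sum)
            m = classification_metrics(pooled_counts)
            agg = MetricsRow(m.sensitivity, m.specificity, m.accuracy, float(np.mean(sq_errors)))
        else:
            agg = MetricsRow(
                float(np.mean([r.sensitivity for r in fold_rows])),
                float(np.mean([r.specificity for r in fold_rows])),
                float(np.mean([r.accuracy for r in fold_rows])),
                float(np.mean(sq_errors)),
            )
        results[spec.kind] = CVResult(spec, fold_rows, agg, fold_assignment)
        rows.append(
            [spec.kind, agg.sensitivity, agg.specificity, agg.accuracy, agg.mse]
        )
    table = pd.DataFrame(
        rows, columns=["classifier", "sensitivity", "specificity", "accuracy", "mse"]
    ).set_index("classifier")
    return results, table.round(TABLE_PRECISION)
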