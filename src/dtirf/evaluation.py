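"""Classifier evaluation: confusion metrics, ROC/AUC, stratified k-fold
cross-validation, (K, L) grid search and cross-model comparison.

Metrics follow the standard confusion-matrix definitions:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    precision   = TP / (TP + FP)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A metric whose denominator is zero is reported as undefined (None) and
excluded from fold averaging with a warning, never coerced to 0.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from dtirf.dataset import DatasetMatrix
from dtirf.rotation_forest import RotationForest, RotationForestConfig

__all__ = [
    "METRIC_NAMES",
    "ConfusionCounts",
    "MetricReport",
    "GridSearchSurface",
    "ComparisonResult",
    "confusion_counts",
    "metrics",
    "roc_auc",
    "kfold_cv",
    "grid_search",
    "compare_models",
    "write_report_tsv",
    "write_roc_tsv",
]

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "mcc", "auc")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    """Per-fold metrics with their mean and (sample) standard deviation.

    ``mean``/``sd`` are recomputed from ``per_fold`` over the folds where a
    metric is defined; ``roc_curves`` holds one (fpr, tpr) point list per
    fold for export.
    """

    per_fold: list[dict[str, float | None]]
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    roc_curves: list[list[tuple[float, float]]] = field(default_factory=list)
    fold_test_indices: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.mean:
            self.mean, self.sd = _aggregate(self.per_fold)

    def to_json(self) -> str:
        return json.dumps(
            {"per_fold": self.per_fold, "mean": self.mean, "sd": self.sd},
            indent=2, sort_keys=True,
        )


@dataclass
class GridSearchSurface:
    """Cross-validated accuracy over a (K, L) grid."""

    K_values: list[int]
    L_values: list[int]
    accuracy: np.ndarray
    best: tuple[int, int]

    def __post_init__(self) -> None:
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        if self.accuracy.shape != (len(self.K_values), len(self.L_values)):
            raise ValueError("accuracy matrix shape does not match the grids")


@dataclass
class ComparisonResult:
    statistic: float
    pvalue: float
    method: str


def confusion_counts(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Exact TP/FP/TN/FN tallies for binary labels."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, precision, sensitivity and MCC from confusion counts.

    Undefined metrics (zero denominator) come back as None.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if counts.total == 0:
        raise ValueError("confusion counts sum to zero")
    out: dict[str, float | None] = {"accuracy": (tp + tn) / counts.total}
    out["precision"] = tp / (tp + fp) if tp + fp > 0 else None
    out["sensitivity"] = tp / (tp + fn) if tp + fn > 0 else None
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    out["mcc"] = (tp * tn - fp * fn) / denom if denom > 0 else None
    return out


def roc_auc(y_true: Sequence[int], scores: Sequence[float]) -> tuple[float, list[tuple[float, float]]]:
    """AUC by trapezoidal integration over all score thresholds.

    Equals the tie-corrected rank statistic U/(n1*n0).  Also returns the
    ROC as a list of (FPR, TPR) points.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("roc_auc needs both classes present")
    fpr, tpr, _ = roc_curve(y_true, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def _aggregate(per_fold: list[dict[str, float | None]]) -> tuple[dict[str, float], dict[str, float]]:
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for name in METRIC_NAMES:
        values = [f[name] for f in per_fold if f.get(name) is not None]
        if len(values) < len(per_fold):
            warnings.warn(f"metric {name!r} undefined in {len(per_fold) - len(values)} fold(s); "
                          "excluded from averaging")
        if values:
            mean[name] = float(np.mean(values))
            sd[name] = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return mean, sd


def kfold_cv(
    dataset: DatasetMatrix,
    classifier_config: RotationForestConfig | None = None,
    k: int = 5,
    seed: int = 0,
    stratified: bool = True,
    classifier_factory: Callable[[int], object] | None = None,
) -> MetricReport:
    """Stratified k-fold cross-validation of a classifier on a dataset.

    The default classifier is a Rotation Forest built from
    ``classifier_config`` with a per-fold seed offset; any estimator with
    fit/predict/predict_proba can be substituted via ``classifier_factory``
    (called with the fold index).  Folds partition the sample index set;
    train and test indices never overlap.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = dataset.y
    class_counts = np.bincount(y)
    if stratified and (class_counts[class_counts > 0] < k).any():
        raise ValueError(f"each class needs at least k={k} members")
    if classifier_config is None:
        classifier_config = RotationForestConfig(seed=seed)
    if classifier_factory is None:
        def classifier_factory(fold: int) -> RotationForest:
            cfg = RotationForestConfig(
                K=classifier_config.K,
                L=classifier_config.L,
                bootstrap_fraction=classifier_config.bootstrap_fraction,
                seed=(classifier_config.seed + fold) % 2**31,
                class_subset=classifier_config.class_subset,
                voting=classifier_config.voting,
                threshold=classifier_config.threshold,
            )
            return RotationForest(cfg)

    splitter_cls = StratifiedKFold if stratified else KFold
    splitter = splitter_cls(n_splits=k, shuffle=True, random_state=seed % 2**31)
    per_fold: list[dict[str, float | None]] = []
    roc_curves: list[list[tuple[float, float]]] = []
    fold_test_indices: list[list[int]] = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(dataset.X, y)):
        assert not set(train_idx) & set(test_idx), "train/test fold leakage"
        fold_test_indices.append([int(i) for i in test_idx])
        clf = classifier_factory(fold)
        clf.fit(dataset.X[train_idx], y[train_idx])
        scores = np.asarray(clf.predict_proba(dataset.X[test_idx]))
        if scores.ndim == 2:  # sklearn-style (n, 2) posteriors
            scores = scores[:, -1]
        y_pred = np.asarray(clf.predict(dataset.X[test_idx]))
        fold_metrics = metrics(confusion_counts(y[test_idx], y_pred))
        auc, points = roc_auc(y[test_idx], scores)
        fold_metrics["auc"] = auc
        per_fold.append(fold_metrics)
        roc_curves.append(points)
    report = MetricReport(per_fold=per_fold)
    report.roc_curves = roc_curves
    report.fold_test_indices = fold_test_indices
    return report


def grid_search(
    dataset: DatasetMatrix,
    K_values: Sequence[int],
    L_values: Sequence[int],
    k: int = 5,
    seed: int = 0,
    bootstrap_fraction: float = 0.75,
) -> GridSearchSurface:
    """Mean CV accuracy for every (K, L); best cell by maximum accuracy,
    ties resolved toward the smallest K, then the smallest L."""
    if not len(K_values) or not len(L_values):
        raise ValueError("K_values and L_values must be nonempty")
    accuracy = np.zeros((len(K_values), len(L_values)))
    best: tuple[int, int] | None = None
    best_acc = -np.inf
    for i, K in enumerate(K_values):
        for j, L in enumerate(L_values):
            cfg = RotationForestConfig(K=K, L=L, bootstrap_fraction=bootstrap_fraction, seed=seed)
            report = kfold_cv(dataset, cfg, k=k, seed=seed)
            accuracy[i, j] = report.mean["accuracy"]
            if accuracy[i, j] > best_acc:
                best_acc = accuracy[i, j]
                best = (K, L)
    return GridSearchSurface(K_values=list(K_values), L_values=list(L_values),
                             accuracy=accuracy, best=best)


def compare_models(metric_table: np.ndarray, method: str = "paired_t") -> ComparisonResult:
    """Paired two-sided test of model 1 against the pooled competitors.

    ``metric_table`` is models x datasets (first row = the model under
    test); competitors are pooled by averaging rows 2..m per dataset, and
    the paired differences are tested across datasets with a paired t-test
    or the Wilcoxon signed-rank test.  All-zero differences give p = 1
    (no evidence of a difference); constant nonzero differences raise,
    since the test statistic is unbounded there.
    """
    table = np.asarray(metric_table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 models and 2 datasets")
    ours = table[0]
    pooled = table[1:].mean(axis=0)
    diffs = ours - pooled
    if np.allclose(diffs, 0):
        return ComparisonResult(statistic=0.0, pvalue=1.0, method=method)
    if np.allclose(diffs, diffs[0]):
        raise ValueError("paired differences are constant; test statistic undefined")
    if method == "paired_t":
        res = scipy.stats.ttest_rel(ours, pooled)
    elif method == "wilcoxon":
        res = scipy.stats.wilcoxon(ours, pooled)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ComparisonResult(statistic=float(res.statistic), pvalue=float(res.pvalue), method=method)


def write_report_tsv(report: MetricReport, path) -> None:
    """Write a report as TSV: one row per fold, then Average and
    Standard Deviation rows (mirroring the usual benchmark-table layout)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("row\t" + "\t".join(METRIC_NAMES) + "\n")
        for i, fold in enumerate(report.per_fold, start=1):
            cells = ["NA" if fold.get(m) is None else repr(float(fold[m])) for m in METRIC_NAMES]
            fh.write(f"fold{i}\t" + "\t".join(cells) + "\n")
        fh.write("Average\t" + "\t".join(
            "NA" if m not in report.mean else repr(report.mean[m]) for m in METRIC_NAMES) + "\n")
        fh.write("Standard Deviation\t" + "\t".join(
            "NA" if m not in report.sd else repr(report.sd[m]) for m in METRIC_NAMES) + "\n")


def write_roc_tsv(points: list[tuple[float, float]], path) -> None:
    """Write ROC points as a two-column fpr/tpr TSV."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in points:
            fh.write(f"{fpr!r}\t{tpr!r}\n")
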