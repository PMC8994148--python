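"""Repeated cross-validation, ROC analysis and external validation.

The evaluation protocol keeps the network structure fixed (it is learned
once, on the full development cohort) and re-estimates only the CPTs
inside each training split.  Per validation fold: predict the outcome
probability for every held-out report, choose the probability threshold
maximising the Youden index (sensitivity + specificity - 1) on that fold,
and record AUC, sensitivity, specificity and accuracy.  Summaries report
the fold mean with a normal-approximation 95% CI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .bn_params import DiscreteBN, fit_mle
from .bn_inference import predict_scores
from .bn_structure import DAG
from .report_io import CaseMatrix

__all__ = [
    "ROCCurve",
    "FoldResult",
    "CVResult",
    "stratified_kfold",
    "roc_curve",
    "auc",
    "youden_threshold",
    "confusion_metrics",
    "repeated_cv",
    "external_validate",
]


@dataclass(frozen=True)
class ROCCurve:
    """Operating points of the rule "positive iff score > threshold".

    Thresholds ascend; TPR and FPR are therefore non-increasing.  The
    first point (threshold below every score) is (1, 1) and the last
    (threshold = max score) is (0, 0).
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray

    def youden(self) -> np.ndarray:
        return self.tpr - self.fpr


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """Empirical ROC curve with ties grouped at a single threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build a ROC curve")

    uniq = np.unique(scores)
    # leading sentinel: a threshold below every score classifies all positive
    thresholds = np.concatenate(([-np.inf], uniq))
    tp = np.empty(thresholds.size)
    fp = np.empty(thresholds.size)
    order = np.argsort(scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = labels[order].astype(np.int64)
    cum_pos = np.concatenate(([0], np.cumsum(sorted_pos)))
    for i, t in enumerate(thresholds):
        # predicted positive: score > t
        k = int(np.searchsorted(sorted_scores, t, side="right"))
        tp[i] = n_pos - cum_pos[k]
        fp[i] = (scores.size - k) - tp[i]
    return ROCCurve(thresholds, tp / n_pos, fp / n_neg)


def auc(curve: ROCCurve) -> float:
    """Area under the ROC curve by the trapezoidal rule.

    Points are ordered by (FPR, TPR) so that vertical segments produced by
    tied scores contribute the correct trapezoid.
    """
    order = np.lexsort((curve.tpr, curve.fpr))
    return float(np.trapezoid(curve.tpr[order], curve.fpr[order]))


def youden_threshold(curve: ROCCurve) -> float:
    """Threshold maximising TPR - FPR; ties go to the smaller threshold.

    Only finite thresholds (actual score values) are candidates: the
    all-positive sentinel point has a Youden value of 0, which the
    all-negative endpoint always matches, so it is never a strict optimum.
    """
    finite = np.isfinite(curve.thresholds)
    j = curve.youden()[finite]
    thresholds = curve.thresholds[finite]
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
    return float(thresholds[best])


def confusion_metrics(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) of "positive iff score > threshold"."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pred = scores > threshold
    tp = int((pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    sens = tp / n_pos if n_pos else float("nan")
    spec = tn / n_neg if n_neg else float("nan")
    acc = (tp + tn) / labels.size
    return sens, spec, acc


def stratified_kfold(
    n: int, labels: Sequence[int], k: int, seed: int
) -> np.ndarray:
    """Fold index (0..k-1) per row; outcome-stratified, deterministic per seed.

    Fold sizes differ by at most one, as do per-fold positive counts.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != n:
        raise ValueError("labels length must equal n")
    if k < 2:
        raise ValueError("k must be >= 2")
    _, class_counts = np.unique(labels, return_counts=True)
    if class_counts.min() < k:
        raise ValueError(
            f"smallest class has {class_counts.min()} members, fewer than k={k}"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(n, dtype=np.int64)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(n), labels)):
        assignment[test_idx] = fold
    return assignment


@dataclass(frozen=True)
class FoldResult:
    repeat: int
    fold: int
    threshold: float
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float


@dataclass
class CVResult:
    folds: list[FoldResult]
    skipped: int = 0

    def _metric(self, name: str) -> np.ndarray:
        return np.array([getattr(f, name) for f in self.folds], dtype=float)

    def summary(self) -> dict[str, dict[str, float]]:
        """Mean and normal-approximation 95% CI per metric over folds."""
        out: dict[str, dict[str, float]] = {}
        k = len(self.folds)
        for name in ("auc", "sensitivity", "specificity", "accuracy", "threshold"):
            values = self._metric(name)
            mean = float(values.mean())
            sd = float(values.std(ddof=1)) if k > 1 else 0.0
            half = 1.96 * sd / math.sqrt(k) if k > 0 else float("nan")
            out[name] = {"mean": mean, "ci_low": mean - half, "ci_high": mean + half}
        return out


def _evaluate_fold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float, float, float]:
    curve = roc_curve(scores, labels)
    fold_auc = auc(curve)
    threshold = youden_threshold(curve)
    sens, spec, acc = confusion_metrics(scores, labels, threshold)
    return threshold, fold_auc, sens, spec, acc


def repeated_cv(
    matrix: CaseMatrix,
    dag: DAG,
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
    fallback: str = "uniform",
    threshold_on: str = "validation",
) -> CVResult:
    """Repeated stratified k-fold CV with the structure held fixed.

    Per fold: CPTs are refit on the k-1 training folds, the held-out fold
    is scored, and the Youden threshold is chosen on the held-out fold
    itself (``threshold_on="validation"``, matching the development
    protocol; "training" chooses it on the training folds instead, a less
    optimistic variant).  Folds whose validation part is single-class are
    skipped and counted.
    """
    if threshold_on not in ("validation", "training"):
        raise ValueError("threshold_on must be 'validation' or 'training'")
    target = matrix.outcome
    labels = matrix.column(target)
    results: list[FoldResult] = []
    skipped = 0
    rng = np.random.default_rng(seed)
    for rep in range(repeats):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        assignment = stratified_kfold(matrix.n, labels, k, fold_seed)
        for fold in range(k):
            val_mask = assignment == fold
            val_labels = labels[val_mask]
            if val_labels.min() == val_labels.max():
                skipped += 1
                continue
            train = matrix.subset_rows(~val_mask)
            bn = fit_mle(dag, train, fallback=fallback)
            scores = predict_scores(bn, matrix.subset_rows(val_mask), target, impossible="parents")
            if threshold_on == "training":
                train_scores = predict_scores(bn, train, target, impossible="parents")
                threshold = youden_threshold(
                    roc_curve(train_scores, labels[~val_mask])
                )
                curve = roc_curve(scores, val_labels)
                fold_auc = auc(curve)
                sens, spec, acc = confusion_metrics(scores, val_labels, threshold)
            else:
                threshold, fold_auc, sens, spec, acc = _evaluate_fold(
                    scores, val_labels
                )
            results.append(
                FoldResult(rep, fold, threshold, fold_auc, sens, spec, acc)
            )
    return CVResult(results, skipped)


def external_validate(
    bn: DiscreteBN,
    matrix: CaseMatrix,
    threshold: float | None = None,
) -> dict[str, float]:
    """Apply a trained network to an external cohort.

    The cohort must provide all network variables (extra columns are
    projected away by :func:`predict_scores`).  By default the threshold
    is chosen by the Youden index on the external cohort's own ROC curve;
    pass ``threshold`` to transfer a development-cohort threshold instead.
    """
    target = matrix.outcome
    labels = matrix.column(target)
    scores = predict_scores(bn, matrix, target, impossible="parents")
    curve = roc_curve(scores, labels)
    if threshold is None:
        threshold = youden_threshold(curve)
    sens, spec, acc = confusion_metrics(scores, labels, threshold)
    return {
        "auc": auc(curve),
        "threshold": float(threshold),
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
    }
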