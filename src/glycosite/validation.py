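"""Evaluation protocol: confusion matrix, Sn/Sp/Acc/MCC, ROC, and the
self-consistency / k-fold cross-validation / jackknife testing regimes.

Metric definitions (TP true positives, FN false negatives, FP false
positives, TN true negatives):

    Sn  = TP / (TP + FN)                         sensitivity
    Sp  = TN / (FP + TN)                         specificity
    Acc = (TP + TN) / (TP + TN + FP + FN)        accuracy
    MCC = (TN*TP - FN*FP) /
          sqrt((FP+TP)(FP+TN)(FN+TP)(FN+TN))     Matthews correlation

A metric whose denominator is zero is reported as *undefined* (None), never
silently zeroed.  Printed four-decimal values in this literature are
truncated, not rounded (0.99949 prints as 0.9994); :func:`truncate`
reproduces that convention.

Cross-validation fold plans are exact partitions: the folds cover the data,
are pairwise disjoint, and differ in size by at most one.  The feature
scaler and the network are fitted strictly inside each training split — the
held-out fold never leaks into fitting.  The jackknife tests each element of
a (sub)sample against a model trained on everything else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import apply_scaler, fit_scaler
from .mlp import TrainConfig, TrainedModel, fit_model


def truncate(value: float, digits: int = 4) -> float:
    """Truncate toward zero at ``digits`` decimals (printing convention)."""
    f = 10 ** digits
    return math.trunc(value * f) / f


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricSet:
    """Sn/Sp/Acc/MCC; None marks a metric undefined (zero denominator)."""

    sn: float | None
    sp: float | None
    acc: float | None
    mcc: float | None


def confusion(labels: Sequence[int], predictions: Sequence[int]
              ) -> ConfusionMatrix:
    """Tally the four outcome counts from parallel label/prediction lists."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    if labels.size == 0:
        raise ValueError("cannot tabulate an empty prediction set")
    return ConfusionMatrix(
        tp=int(np.sum((labels == 1) & (predictions == 1))),
        fn=int(np.sum((labels == 1) & (predictions == 0))),
        fp=int(np.sum((labels == 0) & (predictions == 1))),
        tn=int(np.sum((labels == 0) & (predictions == 0))),
    )


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Sn, Sp, Acc and MCC of a confusion matrix (undefined -> None)."""
    sn = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else None
    sp = cm.tn / (cm.fp + cm.tn) if cm.fp + cm.tn else None
    acc = (cm.tp + cm.tn) / cm.total if cm.total else None
    denom = ((cm.fp + cm.tp) * (cm.fp + cm.tn)
             * (cm.fn + cm.tp) * (cm.fn + cm.tn))
    mcc = ((cm.tn * cm.tp - cm.fn * cm.fp) / math.sqrt(denom)
           if denom else None)
    return MetricSet(sn, sp, acc, mcc)


@dataclass(frozen=True)
class RocCurve:
    """ROC points from a descending score-threshold sweep, plus trapezoid AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """Threshold sweep over the unique scores, descending.

    Starts at (0, 0) (threshold above every score) and ends at (1, 1);
    both coordinates are monotone non-decreasing.  AUC by the trapezoid
    rule, which equals the Mann-Whitney U statistic / (n_pos * n_neg).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    is_pos = (labels[order] == 1).astype(float)
    tp = np.cumsum(is_pos)
    fp = np.cumsum(1.0 - is_pos)
    # keep the last index of each tied-score run
    last = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tp[last] / n_pos]
    fpr = np.r_[0.0, fp[last] / n_neg]
    thresholds = np.r_[np.inf, s[last]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr, tpr, thresholds, auc)


@dataclass(frozen=True)
class FoldPlan:
    """k disjoint index subsets covering 0..n-1, sizes differing by <= 1."""

    folds: tuple[np.ndarray, ...]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)


def kfold_split(n: int, k: int, seed: int = 0) -> FoldPlan:
    """Seeded random partition of 0..n-1 into k balanced folds."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return FoldPlan(tuple(np.sort(f) for f in np.array_split(perm, k)), seed)


def stratified_kfold_split(labels: Sequence[int], k: int,
                           seed: int = 0) -> FoldPlan:
    """Balanced folds preserving the class ratio (round-robin per class)."""
    labels = np.asarray(labels)
    n = labels.size
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    assigned = np.empty(n, dtype=np.int64)
    start = 0
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        # continue the round-robin across classes so fold sizes stay balanced
        assigned[idx] = (np.arange(start, start + idx.size)) % k
        start += idx.size
    folds = tuple(np.flatnonzero(assigned == f) for f in range(k))
    return FoldPlan(folds, seed)


@dataclass
class CVResult:
    fold_accuracies: list[float]
    fold_pos_accuracies: list[float | None]
    fold_neg_accuracies: list[float | None]
    mean_accuracy: float
    plan: FoldPlan
    confusions: list[ConfusionMatrix] = field(default_factory=list)

    @property
    def mean_pos_accuracy(self) -> float:
        vals = [a for a in self.fold_pos_accuracies if a is not None]
        return float(np.mean(vals))

    @property
    def mean_neg_accuracy(self) -> float:
        vals = [a for a in self.fold_neg_accuracies if a is not None]
        return float(np.mean(vals))


def cross_validate(X: np.ndarray, y: np.ndarray, k: int = 10,
                   config: TrainConfig | None = None,
                   hidden: Sequence[int] = (20,),
                   stratified: bool = True) -> CVResult:
    """k-fold cross-validation with per-fold refitting of scaler and network.

    Each iteration trains on k-1 folds and tests the held-out fold; the
    overall result is the mean of the fold accuracies.  Per-class (positive
    and negative site) accuracies are reported alongside the aggregate.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    config = config or TrainConfig()
    plan = (stratified_kfold_split(y, k, config.seed) if stratified
            else kfold_split(len(y), k, config.seed))
    accs: list[float] = []
    pos_accs: list[float | None] = []
    neg_accs: list[float | None] = []
    cms: list[ConfusionMatrix] = []
    all_idx = np.arange(len(y))
    for fold in plan.folds:
        train_idx = np.setdiff1d(all_idx, fold)
        model, _ = fit_model(X[train_idx], y[train_idx], config, hidden)
        pred = model.predict(X[fold])
        cm = confusion(y[fold], pred)
        cms.append(cm)
        accs.append((cm.tp + cm.tn) / cm.total)
        pos_accs.append(cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else None)
        neg_accs.append(cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else None)
    return CVResult(accs, pos_accs, neg_accs, float(np.mean(accs)), plan, cms)


@dataclass
class SelfConsistencyResult:
    model: TrainedModel
    cm: ConfusionMatrix
    metric_set: MetricSet
    roc: RocCurve


def self_consistency(X: np.ndarray, y: np.ndarray,
                     config: TrainConfig | None = None,
                     hidden: Sequence[int] = (20,)) -> SelfConsistencyResult:
    """Resubstitution test: train on all the data, evaluate on all of it."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    model, _ = fit_model(X, y, config, hidden)
    scores = model.scores(X)
    cm = confusion(y, (scores >= model.threshold).astype(int))
    return SelfConsistencyResult(model, cm, metrics(cm),
                                 roc_curve(scores, y))


@dataclass
class JackknifeResult:
    outcomes: np.ndarray        # 1 = left-out sample classified correctly
    tested_indices: np.ndarray
    mean_accuracy: float        # A*


def jackknife(X: np.ndarray, y: np.ndarray,
              subsample_size: int | None = None,
              config: TrainConfig | None = None,
              hidden: Sequence[int] = (20,),
              seed: int = 0) -> JackknifeResult:
    """Leave-one-out testing, optionally estimated on a random subsample.

    For each selected sample, the model is trained on all *other* samples
    in the full dataset and tested on the one left out; the overall
    accuracy A* is the mean of the per-iteration 0/1 outcomes.  A
    ``subsample_size`` below n gives the estimated jackknife used when full
    leave-one-out is too expensive.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    config = config or TrainConfig()
    if subsample_size is None:
        subsample_size = n
    if subsample_size > n:
        raise ValueError(f"subsample {subsample_size} exceeds dataset size {n}")
    rng = np.random.default_rng(seed)
    tested = (np.arange(n) if subsample_size == n
              else np.sort(rng.choice(n, size=subsample_size, replace=False)))
    outcomes = np.empty(len(tested), dtype=np.int64)
    all_idx = np.arange(n)
    for j, i in enumerate(tested):
        train_idx = all_idx[all_idx != i]
        model, _ = fit_model(X[train_idx], y[train_idx], config, hidden)
        outcomes[j] = int(model.predict(X[i][None, :])[0] == y[i])
    return JackknifeResult(outcomes, tested, float(outcomes.mean()))


def write_roc_tsv(roc: RocCurve, path: str) -> None:
    """ROC points as TSV (threshold, fpr, tpr) for external plotting."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("threshold\tfpr\ttpr\n")
        for t, f, tp in zip(roc.thresholds, roc.fpr, roc.tpr):
            fh.write(f"{t}\t{f}\t{tp}\n")
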