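"""Stratified K-fold cross-validation, metrics, and rater comparison.

Metrics follow the standard confusion-matrix definitions:
accuracy = (TP + TN) / (TP + FP + FN + TN), precision = TP / (TP + FP),
recall = TP / (TP + FN), F1 = harmonic mean of precision and recall.
Per-task scores default to macro averaging over the two classes;
positive-class averaging is available. Classifier-vs-rater accuracy
comparisons use the Pearson chi-square test on the 2x2
correct/incorrect table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from pulmokit.ensemble_model import (
    EnsembleSpec,
    TaskSpec,
    TrainedEnsemble,
    map_labels,
    predict,
    train_ensemble,
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive_class: str) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=object)
        y_pred = np.asarray(y_pred, dtype=object)
        if y_true.size != y_pred.size:
            raise ValueError("y_true and y_pred must have equal length")
        pos_t = y_true == positive_class
        pos_p = y_pred == positive_class
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
        )

    def swapped(self) -> "ConfusionCounts":
        """Counts with the positive/negative roles exchanged."""
        return ConfusionCounts(self.tn, self.fn, self.fp, self.tp)


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float
    averaging: str = "macro"
    undefined_flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "averaging": self.averaging,
            "undefined_flags": list(self.undefined_flags),
        }


def _safe_div(num: float, den: float, name: str, flags: list) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts, averaging: str = "positive_class") -> MetricSet:
    """Metrics from confusion counts.

    positive_class: precision/recall/F1 of the positive class only.
    macro: unweighted mean of the two per-class values. Zero-denominator
    ratios are reported as 0 and flagged.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics on empty counts")
    if averaging not in ("positive_class", "macro"):
        raise ValueError(f"unknown averaging {averaging!r}")
    flags: list[str] = []
    accuracy = (counts.tp + counts.tn) / counts.total

    def prf(c: ConfusionCounts, side: str) -> tuple[float, float, float]:
        p = _safe_div(c.tp, c.tp + c.fp, f"precision_{side}", flags)
        r = _safe_div(c.tp, c.tp + c.fn, f"recall_{side}", flags)
        f = _safe_div(2 * p * r, p + r, f"f1_{side}", flags)
        return p, r, f

    if averaging == "positive_class":
        p, r, f = prf(counts, "pos")
    else:
        p1, r1, f1_ = prf(counts, "pos")
        p2, r2, f2_ = prf(counts.swapped(), "neg")
        p, r, f = (p1 + p2) / 2, (r1 + r2) / 2, (f1_ + f2_) / 2
    return MetricSet(accuracy, p, r, f, averaging, tuple(flags))


def stratified_folds(labels, K: int, seed: int = 0) -> np.ndarray:
    """Fold index (0..K-1) per sample; class proportions preserved per fold.

    Every fold's per-class count differs from the proportional share
    n_class / K by less than one sample.
    """
    labels = np.asarray(labels, dtype=object)
    if K < 2:
        raise ValueError("K must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    too_small = classes[counts < K]
    if too_small.size:
        raise ValueError(
            f"every class needs >= K={K} samples; too small: {list(too_small)}"
        )
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    assignment = np.empty(labels.size, dtype=int)
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
        assignment[val_idx] = fold
    return assignment


@dataclass(frozen=True)
class CVReport:
    K: int
    task: TaskSpec
    fold_metrics: tuple[MetricSet, ...]
    pooled: MetricSet
    pooled_counts: ConfusionCounts
    fold_assignment: tuple[int, ...]
    seed: int

    def as_dict(self) -> dict:
        return {
            "task": self.task.task_id,
            "K": self.K,
            "seed": self.seed,
            "pooled": self.pooled.as_dict(),
            "folds": [m.as_dict() for m in self.fold_metrics],
        }


def cross_validate(
    X: np.ndarray,
    labels,
    task: TaskSpec,
    spec: EnsembleSpec | None = None,
    K: int = 10,
    seed: int = 0,
    averaging: str = "macro",
) -> tuple[CVReport, list[TrainedEnsemble]]:
    """Stratified K-fold cross-validation of the voting ensemble.

    Rows are first mapped/filtered for the task, then split into K
    stratified folds; each fold serves once as validation. Pooled
    metrics are computed over the union of all validation predictions
    (equivalently: the sum of per-fold confusion counts). Returns the
    report plus the K fold ensembles (inputs to the overall nested
    ensemble).
    """
    if spec is None:
        spec = EnsembleSpec.for_task(task)
    X = np.asarray(X, dtype=np.float64)
    y, mask = map_labels(labels, task)
    Xt = X[mask]
    assignment = stratified_folds(y, K, seed)
    fold_seeds = np.random.SeedSequence(seed).generate_state(K) % (2**31)

    fold_metrics = []
    fold_ensembles = []
    pooled_counts = ConfusionCounts(0, 0, 0, 0)
    for fold in range(K):
        val = assignment == fold
        ens = train_ensemble(Xt[~val], y[~val], task, spec, seed=int(fold_seeds[fold]))
        y_pred = predict(ens, Xt[val])
        counts = ConfusionCounts.from_predictions(y[val], y_pred, task.positive_class)
        fold_metrics.append(compute_metrics(counts, averaging))
        pooled_counts = pooled_counts + counts
        fold_ensembles.append(ens)

    report = CVReport(
        K=K,
        task=task,
        fold_metrics=tuple(fold_metrics),
        pooled=compute_metrics(pooled_counts, averaging),
        pooled_counts=pooled_counts,
        fold_assignment=tuple(int(a) for a in assignment),
        seed=seed,
    )
    return report, fold_ensembles


def evaluate_prospective(
    ensemble: TrainedEnsemble,
    X: np.ndarray,
    labels,
    averaging: str = "macro",
) -> MetricSet:
    """Score a (typically overall/nested) ensemble on a held-out set."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] == 0:
        raise ValueError("prospective set is empty")
    y, mask = map_labels(labels, ensemble.task)
    if y.size == 0:
        raise ValueError("no rows retained for this task")
    y_pred = predict(ensemble, X[mask])
    counts = ConfusionCounts.from_predictions(y, y_pred, ensemble.task.positive_class)
    return compute_metrics(counts, averaging)


@dataclass(frozen=True)
class RaterComparison:
    model_correct: int
    model_total: int
    rater_correct: int
    rater_total: int
    chi_square_statistic: float
    p_value: float
    continuity_correction: bool


def compare_raters(
    model_correct: int,
    model_total: int,
    rater_correct: int,
    rater_total: int,
    continuity_correction: bool = False,
) -> RaterComparison:
    """Pearson chi-square comparing model vs. rater accuracy.

    Tests homogeneity of the two correct/incorrect proportions on the
    2x2 table [[model_correct, model_incorrect],
    [rater_correct, rater_incorrect]], 1 degree of freedom.
    """
    if model_total <= 0 or rater_total <= 0:
        raise ValueError("totals must be positive")
    if not 0 <= model_correct <= model_total or not 0 <= rater_correct <= rater_total:
        raise ValueError("correct counts must lie in [0, total]")
    table = np.array(
        [
            [model_correct, model_total - model_correct],
            [rater_correct, rater_total - rater_correct],
        ]
    )
    if model_correct / model_total == rater_correct / rater_total:
        stat, p = 0.0, 1.0  # identical proportions: exact homogeneity
    else:
        stat, p, _, _ = stats.chi2_contingency(table, correction=continuity_correction)
    return RaterComparison(
        model_correct,
        model_total,
        rater_correct,
        rater_total,
        float(stat),
        float(p),
        continuity_correction,
    )
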