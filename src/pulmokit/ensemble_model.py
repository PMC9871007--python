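"""Majority-voting ensembles of RBF-kernel SVMs for four binary tasks.

Tasks: (1) normal vs. abnormal, (2) crackles vs. wheezing,
(3) normal vs. crackles, (4) normal vs. wheezing. Default ensemble
sizes are 1, 4, 10 and 4 members respectively; members differ by
seeded bootstrap resamples of the training rows (bagging) and emit
class probabilities. An ensemble predicts the class with the majority
of member votes; ties (even ensembles) go to the class with the higher
mean member probability. The "overall" ensemble used for prospective
validation concatenates every member from every cross-validation fold.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from pulmokit.synth import LABELS

TASK_IDS = (
    "normal_vs_abnormal",
    "crackles_vs_wheezing",
    "normal_vs_crackles",
    "normal_vs_wheezing",
)

#: default member counts per task, in TASK_IDS order
DEFAULT_N_MEMBERS = {
    "normal_vs_abnormal": 1,
    "crackles_vs_wheezing": 4,
    "normal_vs_crackles": 10,
    "normal_vs_wheezing": 4,
}

_TASK_CLASSES = {
    "normal_vs_abnormal": ("normal", "abnormal"),
    "crackles_vs_wheezing": ("crackles", "wheezing"),
    "normal_vs_crackles": ("normal", "crackles"),
    "normal_vs_wheezing": ("normal", "wheezing"),
}


@dataclass(frozen=True)
class TaskSpec:
    """One of the four binary classification tasks.

    positive_class is the second element of the task's class pair (the
    adventitious / abnormal side).
    """

    task_id: str

    def __post_init__(self) -> None:
        if self.task_id not in TASK_IDS:
            raise ValueError(f"task_id must be one of {TASK_IDS}, got {self.task_id!r}")

    @property
    def negative_class(self) -> str:
        return _TASK_CLASSES[self.task_id][0]

    @property
    def positive_class(self) -> str:
        return _TASK_CLASSES[self.task_id][1]

    @classmethod
    def from_number(cls, number: int) -> "TaskSpec":
        """Task by its conventional 1-based number."""
        if not 1 <= number <= 4:
            raise ValueError("task number must be in 1..4")
        return cls(TASK_IDS[number - 1])


def map_labels(labels, task: TaskSpec) -> tuple[np.ndarray, np.ndarray]:
    """Map 3-class labels to the task's binary labels.

    Returns (binary_labels, retained_mask). normal_vs_abnormal retains
    every row and maps {crackles, wheezing} -> "abnormal"; the other
    tasks drop the class that does not participate. binary_labels has
    one entry per *retained* row.
    """
    labels = np.asarray(labels, dtype=object)
    bad = set(labels) - set(LABELS) - {"abnormal"}  # idempotent on mapped labels
    if bad:
        raise ValueError(f"unknown labels: {sorted(map(str, bad))}")
    if task.task_id == "normal_vs_abnormal":
        mask = np.ones(labels.size, dtype=bool)
        binary = np.where(labels == "normal", "normal", "abnormal")
    else:
        keep = set(_TASK_CLASSES[task.task_id])
        mask = np.array([lab in keep for lab in labels])
        binary = labels[mask]
    if len(set(binary)) < 2:
        warnings.warn(
            f"task {task.task_id}: retained rows contain a single class",
            stacklevel=2,
        )
    return np.asarray(binary, dtype=object), mask


@dataclass(frozen=True)
class EnsembleSpec:
    n_members: int = 4
    C: float = 1.0
    gamma: float | str = "scale"
    resample_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= self.n_members <= 10:
            raise ValueError("n_members must lie in [1, 10]")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not 0.0 < self.resample_fraction <= 1.0:
            raise ValueError("resample_fraction must lie in (0, 1]")

    @classmethod
    def for_task(cls, task: TaskSpec, **kwargs) -> "EnsembleSpec":
        kwargs.setdefault("n_members", DEFAULT_N_MEMBERS[task.task_id])
        return cls(**kwargs)


@dataclass(frozen=True)
class VoteOutcome:
    per_member_probabilities: tuple[float, ...]  # P(positive class), per member
    majority_label: str
    mean_probability: float


@dataclass(frozen=True)
class TrainedEnsemble:
    members: tuple[Pipeline, ...]
    spec: EnsembleSpec
    task: TaskSpec
    member_seeds: tuple[int, ...]
    data_fingerprint: str

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError("ensemble must have at least one member")

    @property
    def n_members(self) -> int:
        return len(self.members)


def _fingerprint(X: np.ndarray, y: np.ndarray, seeds) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(",".join(map(str, y)).encode())
    h.update(np.asarray(seeds).tobytes())
    return h.hexdigest()[:16]


def train_member(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    gamma: float | str = "scale",
    seed: int = 0,
    resample_fraction: float = 1.0,
) -> Pipeline:
    """Fit one probabilistic RBF-SVM on a seeded bootstrap resample.

    Features are standardized (zero mean, unit variance, fit on the
    member's resample) before the RBF kernel: MFCC coefficients span
    orders of magnitude and would otherwise dominate the kernel
    distance unevenly.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=object)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training data must contain two classes")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 training samples")
    rng = np.random.default_rng(seed)
    n_draw = max(int(round(resample_fraction * X.shape[0])), 2)
    for _ in range(100):  # redraw if the bootstrap lost a class
        idx = rng.integers(0, X.shape[0], size=n_draw)
        if np.unique(y[idx]).size == 2:
            break
    else:
        raise RuntimeError("could not draw a two-class bootstrap sample")
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                SVC(
                    kernel="rbf",
                    C=C,
                    gamma=gamma,
                    probability=True,
                    random_state=int(seed) % (2**31),
                ),
            ),
        ]
    )
    with warnings.catch_warnings():
        # members must expose probabilities (the tie-break uses them);
        # SVC(probability=True) still does exactly that
        warnings.filterwarnings(
            "ignore", message=".*`probability` parameter.*", category=FutureWarning
        )
        model.fit(X[idx], y[idx])
    return model


def train_ensemble(
    X: np.ndarray,
    labels,
    task: TaskSpec,
    spec: EnsembleSpec | None = None,
    seed: int = 0,
) -> TrainedEnsemble:
    """Train a majority-voting ensemble for one binary task.

    Rows are mapped/filtered by the task; each member trains on its own
    seeded bootstrap resample of the retained rows.
    """
    if spec is None:
        spec = EnsembleSpec.for_task(task)
    X = np.asarray(X, dtype=np.float64)
    y, mask = map_labels(labels, task)
    Xt = X[mask]
    member_seeds = tuple(
        int(s) for s in np.random.SeedSequence(seed).generate_state(spec.n_members) % (2**31)
    )
    members = tuple(
        train_member(Xt, y, spec.C, spec.gamma, s, spec.resample_fraction)
        for s in member_seeds
    )
    return TrainedEnsemble(
        members=members,
        spec=spec,
        task=task,
        member_seeds=member_seeds,
        data_fingerprint=_fingerprint(Xt, y, member_seeds),
    )


def _positive_probability(model: Pipeline, X: np.ndarray, positive_class: str) -> np.ndarray:
    pos_col = list(model.classes_).index(positive_class)
    return model.predict_proba(X)[:, pos_col]


def vote(ensemble: TrainedEnsemble, feature_vector: np.ndarray) -> VoteOutcome:
    """Majority vote of the members on one feature vector.

    Each member votes for the class with probability > 0.5; the
    majority class wins. Even splits are broken by the higher mean
    member probability (mean P(positive) >= 0.5 -> positive).
    """
    x = np.asarray(feature_vector, dtype=np.float64).reshape(1, -1)
    expected = ensemble.members[0].n_features_in_
    if x.shape[1] != expected:
        raise ValueError(
            f"feature vector has {x.shape[1]} dimensions, ensemble expects {expected}"
        )
    pos = ensemble.task.positive_class
    neg = ensemble.task.negative_class
    probs = tuple(float(_positive_probability(m, x, pos)[0]) for m in ensemble.members)
    votes_pos = sum(p > 0.5 for p in probs)
    votes_neg = len(probs) - votes_pos
    mean_p = float(np.mean(probs))
    if votes_pos > votes_neg:
        label = pos
    elif votes_neg > votes_pos:
        label = neg
    else:
        label = pos if mean_p >= 0.5 else neg
    return VoteOutcome(probs, label, mean_p)


def predict(ensemble: TrainedEnsemble, X: np.ndarray) -> np.ndarray:
    """Vectorized majority-vote prediction over rows of X."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != ensemble.members[0].n_features_in_:
        raise ValueError("X must be 2-D with the ensemble's feature dimension")
    pos = ensemble.task.positive_class
    neg = ensemble.task.negative_class
    P = np.stack(
        [_positive_probability(m, X, pos) for m in ensemble.members]
    )  # (members, n)
    votes_pos = (P > 0.5).sum(axis=0)
    votes_neg = P.shape[0] - votes_pos
    mean_p = P.mean(axis=0)
    out = np.where(
        votes_pos > votes_neg,
        pos,
        np.where(votes_neg > votes_pos, neg, np.where(mean_p >= 0.5, pos, neg)),
    )
    return out.astype(object)


def build_overall_ensemble(fold_ensembles) -> TrainedEnsemble:
    """Pool every member from every fold into one nested ensemble.

    The K fold ensembles trained during cross-validation contribute all
    their members (K x n_members total); the voting rule is unchanged.
    """
    fold_ensembles = list(fold_ensembles)
    if not fold_ensembles:
        raise ValueError("need at least one fold ensemble")
    tasks = {e.task.task_id for e in fold_ensembles}
    if len(tasks) != 1:
        raise ValueError(f"fold ensembles mix tasks: {sorted(tasks)}")
    dims = {e.members[0].n_features_in_ for e in fold_ensembles}
    if len(dims) != 1:
        raise ValueError(f"fold ensembles mix feature dimensions: {sorted(dims)}")
    members = tuple(m for e in fold_ensembles for m in e.members)
    seeds = tuple(s for e in fold_ensembles for s in e.member_seeds)
    first = fold_ensembles[0]
    return TrainedEnsemble(
        members=members,
        spec=first.spec,
        task=first.task,
        member_seeds=seeds,
        data_fingerprint="+".join(e.data_fingerprint for e in fold_ensembles),
    )
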