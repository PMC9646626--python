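"""RBF-SVM training, LOSO grid search and subject-safe data partitions.

The classifier solves the soft-margin SVM problem — minimize
``1/2 ||w||^2 + C * sum(xi)`` subject to ``y_i (w . phi(x_i) + b) >= 1 - xi_i``
— under the Gaussian kernel ``K(x, x') = exp(-gamma ||x - x'||^2)``,
where ``gamma = 1/(2 sigma^2)`` is the inverse radius of influence of the
support vectors.  Features are z-scored with training-fold statistics
before the kernel (heterogeneous units otherwise dominate the distance);
the statistics are stored so test data always uses training statistics.

Hyperparameters come from fixed task-specific grids searched under
leave-one-subject-out cross-validation: fold-mean accuracy selects for
the artifacts task, pooled-prediction F1 for the apnea task (F1 is
ill-defined on tiny single-subject folds).  Ties prefer smaller C, then
smaller gamma (smoother models).

Two partition schemes keep train and test independent despite window
overlap: leave-30%-of-subjects-out (artifacts) and a per-subject
recording-thirds split with border windows dropped (apnea).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from .io import ValidationError
from .selection import loso_folds

logger = logging.getLogger(__name__)

#: Printed hyperparameter grids per task.
C_GRID = {
    "artifacts": (0.5, 1, 4, 6, 8, 16, 32, 64, 80, 128),
    "apnea": (0.125, 0.75, 1, 2, 3, 4, 5, 6, 8, 32),
}
GAMMA_GRID = tuple(2.0**e for e in (-15, -13, -11, -9, -7, -5, -3, -1, 1, 3))

#: Iteration cap for the SVM solver; near-degenerate grid corners (e.g.
#: gamma = 2^-15, nearly constant kernel) otherwise dominate runtime.
SVC_MAX_ITER = 200_000


@dataclass(frozen=True)
class SvmConfig:
    C: float
    gamma: float
    task: str = "artifacts"

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValidationError("C and gamma must be > 0")


class RbfSvmClassifier(ClassifierMixin, BaseEstimator):
    """Soft-margin RBF-SVM with built-in training-set standardization.

    Parameters
    ----------
    C : float
        Slack penalty; small C widens the margin, large C penalizes
        misclassification.
    gamma : float
        Kernel width parameter, ``1/(2 sigma^2)``.

    Fitted attributes: ``mean_``, ``scale_`` (per-feature training
    statistics), ``svc_`` (the fitted solver), ``classes_``,
    ``feature_names_in_`` when fit on a DataFrame.
    """

    def __init__(self, C: float = 1.0, gamma: float = 0.5):
        self.C = C
        self.gamma = gamma

    def _validate(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be 2-dimensional")
        if not np.all(np.isfinite(X)):
            raise ValidationError("X contains non-finite values")
        return X

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns)
        Xv = self._validate(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValidationError("training labels contain a single class")
        self.mean_ = Xv.mean(axis=0)
        self.scale_ = Xv.std(axis=0)
        self.scale_[self.scale_ == 0] = 1.0
        Z = (Xv - self.mean_) / self.scale_
        self.svc_ = SVC(
            C=self.C, gamma=self.gamma, kernel="rbf",
            cache_size=256, max_iter=SVC_MAX_ITER,
        )
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # iteration-cap convergence notices
            self.svc_.fit(Z, y)
        self.classes_ = self.svc_.classes_
        return self

    def _align(self, X):
        """Reorder DataFrame columns by the training schema (by name)."""
        if isinstance(X, pd.DataFrame) and hasattr(self, "feature_names_in_"):
            missing = [c for c in self.feature_names_in_ if c not in X.columns]
            if missing:
                raise ValidationError(f"missing feature column(s): {missing}")
            X = X[list(self.feature_names_in_)]
        return X

    def decision_function(self, X):
        X = self._validate(self._align(X))
        return self.svc_.decision_function((X - self.mean_) / self.scale_)

    def predict(self, X):
        X = self._validate(self._align(X))
        return self.svc_.predict((X - self.mean_) / self.scale_)


@dataclass
class TrainedModel:
    """A fitted task model: configuration, feature subset, decision rule."""

    config: SvmConfig
    selected_features: list[str]
    classifier: RbfSvmClassifier

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.classifier.predict(table[self.selected_features])


def train_svm_rbf(X, y, cfg: SvmConfig) -> RbfSvmClassifier:
    """Fit the soft-margin RBF-SVM at the given hyperparameters."""
    return RbfSvmClassifier(C=cfg.C, gamma=cfg.gamma).fit(X, y)


def _pooled_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == -1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == -1)))
    if 2 * tp + fp + fn == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


def loso_grid_search(
    table: pd.DataFrame,
    task: str,
    features: list[str],
    C_grid=None,
    gamma_grid=GAMMA_GRID,
) -> SvmConfig:
    """Evaluate every (C, gamma) pair by LOSO over training subjects.

    Selection criterion: fold-mean accuracy (artifacts) or F1 on pooled
    LOSO predictions (apnea).  Iterating the grid in ascending (C, gamma)
    order with strict improvement implements the smaller-C, then
    smaller-gamma tie-break.
    """
    if C_grid is None:
        C_grid = C_GRID[task]
    groups = table["subject"].to_numpy()
    if np.unique(groups).size < 2:
        raise ValidationError("grid search needs >= 2 training subjects")
    X = table[features].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    folds = [(tr, te) for tr, te in loso_folds(groups)]

    best: tuple[float, SvmConfig] | None = None
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            fold_acc = []
            pooled_true, pooled_pred = [], []
            degenerate = False
            for train_mask, test_mask in folds:
                if np.unique(y[train_mask]).size < 2:
                    degenerate = True
                    break
                model = RbfSvmClassifier(C=C, gamma=gamma).fit(
                    X[train_mask], y[train_mask]
                )
                pred = model.predict(X[test_mask])
                fold_acc.append(float(np.mean(pred == y[test_mask])))
                pooled_true.append(y[test_mask])
                pooled_pred.append(pred)
            if degenerate:
                continue
            if task == "apnea":
                score = _pooled_f1(
                    np.concatenate(pooled_true), np.concatenate(pooled_pred)
                )
            else:
                score = float(np.mean(fold_acc))
            if best is None or score > best[0]:
                best = (score, SvmConfig(C=float(C), gamma=float(gamma), task=task))
    if best is None:
        raise ValidationError("grid search exhausted with all-degenerate fits")
    return best[1]


# ---------------------------------------------------------------------------
# partitions
# ---------------------------------------------------------------------------

@dataclass
class PartitionPlan:
    """Train/test keys for one repetition; disjoint at the grouping level."""

    repetition: int
    train_keys: list = field(default_factory=list)
    test_keys: list = field(default_factory=list)


def partition_leave_30pct_subjects(
    subjects: list[str], seed: int, repetition: int = 0
) -> PartitionPlan:
    """Leave-30%-of-subjects-out: round(0.30 n) subjects form the test set.

    All recordings of a subject travel together; sampling is uniform
    without replacement, seeded.
    """
    subjects = list(subjects)
    n = len(subjects)
    if n < 4:
        raise ValidationError("leave-30%-of-subjects-out needs >= 4 subjects")
    n_test = int(round(0.30 * n))
    if n_test < 1:
        raise ValidationError("too few subjects to leave >= 1 for testing")
    rng = np.random.default_rng(seed)
    test = set(rng.choice(np.asarray(subjects, dtype=object), size=n_test, replace=False))
    return PartitionPlan(
        repetition=repetition,
        train_keys=[s for s in subjects if s not in test],
        test_keys=[s for s in subjects if s in test],
    )


def partition_recording_thirds(
    table: pd.DataFrame, repetition: int
) -> PartitionPlan:
    """Leave-1/3-of-recording-out per subject for the apnea task.

    Each subject's breath-hold recording is cut into three contiguous
    equal-duration segments; windows whose span crosses a segment border
    are dropped from both sides; segment ``repetition mod 3`` goes to
    test, the others to train.  Keys are (recording, window_start_s)
    tuples.

    Raises
    ------
    ValidationError
        If any subject's segment ends up without one of the classes
        (named in the message).
    """
    test_seg = repetition % 3
    train_keys: list[tuple[str, float]] = []
    test_keys: list[tuple[str, float]] = []
    for subject, sub in table.groupby("subject"):
        if sub["recording"].nunique() != 1:
            raise ValidationError(
                f"subject {subject!r} must have exactly one breath-hold recording"
            )
        W = float(sub["W"].iloc[0])
        span = float(sub["window_start_s"].max()) + W
        borders = [span / 3.0, 2.0 * span / 3.0]
        seg_labels: dict[int, set[int]] = {0: set(), 1: set(), 2: set()}
        for _, row in sub.iterrows():
            w0 = float(row["window_start_s"])
            w1 = w0 + W
            if w1 <= borders[0]:
                seg = 0
            elif w0 >= borders[0] and w1 <= borders[1]:
                seg = 1
            elif w0 >= borders[1]:
                seg = 2
            else:
                continue  # straddles a border: dropped from both sides
            key = (row["recording"], w0)
            seg_labels[seg].add(int(row["label"]))
            (test_keys if seg == test_seg else train_keys).append(key)
        for seg, labs in seg_labels.items():
            if labs != {-1, 1}:
                raise ValidationError(
                    f"subject {subject!r}: segment {seg} lacks a class"
                )
    return PartitionPlan(repetition=repetition, train_keys=train_keys, test_keys=test_keys)


def split_by_plan(
    table: pd.DataFrame, plan: PartitionPlan, level: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Materialize a plan: ``level`` is 'subject' or 'window'."""
    if level == "subject":
        train = table[table["subject"].isin(plan.train_keys)]
        test = table[table["subject"].isin(plan.test_keys)]
    elif level == "window":
        keys = list(zip(table["recording"], table["window_start_s"].astype(float)))
        train_set, test_set = set(plan.train_keys), set(plan.test_keys)
        in_train = [k in train_set for k in keys]
        in_test = [k in test_set for k in keys]
        train, test = table[in_train], table[in_test]
    else:
        raise ValueError(f"unknown level {level!r}")
    return train.reset_index(drop=True), test.reset_index(drop=True)
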