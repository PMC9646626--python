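"""Chi-square feature ranking and forward sequential selection.

Ranking: each continuous feature is discretized into 10 equal-frequency
bins (computed on training data only) and tested for independence
against the binary label with a chi-square contingency test; features
are sorted by ascending p-value, ties broken by feature index.

Forward selection: the top-30 ranked features form the base set; the
remaining candidates are offered in rank order and a candidate is
accepted while it reduces the leave-one-subject-out misclassification
error (1 - accuracy on concatenated LOSO predictions) by a relative
tolerance of at least 1e-6.  The search stops at the first candidate
failing the tolerance.  Both stages see training subjects only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.base import BaseEstimator

from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

N_BINS = 10
TOP_K = 30
REL_TOL = 1e-6


@dataclass
class FeatureRanking:
    """Features ordered by ascending chi-square p-value."""

    ordered: list[str]
    p_values: dict[str, float]

    def top(self, k: int) -> list[str]:
        return self.ordered[:k]


@dataclass
class SelectedSubset:
    """Accepted feature set (base top-30 plus accepted candidates)."""

    features: list[str]
    cv_error: float
    audit: pd.DataFrame = field(default_factory=pd.DataFrame)


def _chi2_pvalue(values: np.ndarray, y: np.ndarray) -> float:
    """p-value of the label-vs-bin independence test for one feature."""
    if np.unique(values).size < 2:
        return 1.0  # uninformative constant feature
    # 10 equal-frequency bins; duplicate edges collapse on skewed features
    binned = pd.qcut(values, q=N_BINS, labels=False, duplicates="drop")
    if np.unique(binned).size < 2:
        return 1.0
    table = pd.crosstab(binned, y)
    _, p, _, _ = chi2_contingency(table.to_numpy())
    return float(p)


class ChiSquareRanker(BaseEstimator):
    """Rank features by chi-square dependence with the class label.

    Fitted attributes: ``ranking_`` (:class:`FeatureRanking`),
    ``p_values_`` (ndarray aligned with ``feature_names``).
    """

    def __init__(self, feature_names: list[str] | None = None):
        self.feature_names = feature_names

    def fit(self, X, y):
        names = self.feature_names or list(FEATURE_NAMES)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[1] != len(names):
            raise ValueError(
                f"X has {X.shape[1]} columns, expected {len(names)} features"
            )
        pvals = np.array([_chi2_pvalue(X[:, j], y) for j in range(X.shape[1])])
        constant = [names[j] for j in range(X.shape[1]) if pvals[j] == 1.0
                    and np.unique(X[:, j]).size < 2]
        if constant:
            logger.info("constant features assigned p=1: %s", constant)
        # ascending p, ties broken by feature index (stable sort)
        order = np.argsort(pvals, kind="stable")
        self.p_values_ = pvals
        self.ranking_ = FeatureRanking(
            ordered=[names[j] for j in order],
            p_values={names[j]: float(pvals[j]) for j in range(len(names))},
        )
        return self


def chi2_rank(table: pd.DataFrame, feature_names: list[str] | None = None) -> FeatureRanking:
    """Rank the feature columns of a labelled window table."""
    names = feature_names or list(FEATURE_NAMES)
    ranker = ChiSquareRanker(feature_names=names)
    ranker.fit(table[names].to_numpy(), table["label"].to_numpy())
    return ranker.ranking_


def loso_folds(groups: np.ndarray):
    """Leave-one-subject-out index masks (test mask per unique group)."""
    for g in pd.unique(groups):
        yield groups != g, groups == g


def _loso_error(X: np.ndarray, y: np.ndarray, groups: np.ndarray, make_model) -> float:
    """1 - accuracy on concatenated LOSO predictions."""
    correct = 0
    total = 0
    for train_mask, test_mask in loso_folds(groups):
        model = make_model()
        model.fit(X[train_mask], y[train_mask])
        pred = model.predict(X[test_mask])
        correct += int(np.sum(pred == y[test_mask]))
        total += int(test_mask.sum())
    return 1.0 - correct / total


class ForwardFeatureSelector(BaseEstimator):
    """Forward sequential addition on top of the chi-square top-30 base set.

    Parameters
    ----------
    ranking : FeatureRanking
        Complete 51-feature ranking from training data.
    model_factory : callable
        Zero-argument callable returning an unfitted classifier
        (the SVM at the hyperparameters fixed for selection).
    rel_tol : float
        Relative error-decrease tolerance; the first candidate below it
        stops the search.

    Fitted attributes: ``selected_features_``, ``cv_error_``, ``audit_``.
    """

    def __init__(self, ranking: FeatureRanking, model_factory,
                 top_k: int = TOP_K, rel_tol: float = REL_TOL):
        self.ranking = ranking
        self.model_factory = model_factory
        self.top_k = top_k
        self.rel_tol = rel_tol

    def fit(self, table: pd.DataFrame, y=None, groups=None):
        y = table["label"].to_numpy() if y is None else np.asarray(y)
        groups = table["subject"].to_numpy() if groups is None else np.asarray(groups)
        if np.unique(groups).size < 2:
            raise ValueError("forward selection needs >= 2 subjects for LOSO")
        base = self.ranking.top(self.top_k)
        candidates = self.ranking.ordered[self.top_k:]
        current = list(base)
        err = _loso_error(
            table[current].to_numpy(), y, groups, self.model_factory
        )
        audit_rows = []
        for cand in candidates:
            trial = current + [cand]
            trial_err = _loso_error(
                table[trial].to_numpy(), y, groups, self.model_factory
            )
            decrease = (err - trial_err) / err if err > 0 else 0.0
            accepted = decrease >= self.rel_tol
            audit_rows.append(
                {
                    "step": len(audit_rows) + 1,
                    "candidate": cand,
                    "cv_error_before": err,
                    "cv_error_after": trial_err,
                    "accepted": accepted,
                }
            )
            if not accepted:
                break
            current = trial
            err = trial_err
        self.selected_features_ = current
        self.cv_error_ = err
        self.audit_ = pd.DataFrame(audit_rows)
        return self


def forward_select(
    ranking: FeatureRanking,
    table: pd.DataFrame,
    model_factory,
    top_k: int = TOP_K,
    rel_tol: float = REL_TOL,
) -> SelectedSubset:
    """Functional wrapper over :class:`ForwardFeatureSelector`."""
    selector = ForwardFeatureSelector(
        ranking, model_factory, top_k=top_k, rel_tol=rel_tol
    )
    selector.fit(table)
    return SelectedSubset(
        features=selector.selected_features_,
        cv_error=selector.cv_error_,
        audit=selector.audit_,
    )
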