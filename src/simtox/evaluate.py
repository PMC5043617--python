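"""Min-score ensembling, stratified cross-validation and ROC/AUC evaluation.

Cross-validation uses a stratified 13-fold default: within each class the
records are shuffled (seeded) and dealt round-robin to folds, so every fold's
active count differs from any other's by at most one — essential when actives
are a few percent of the data.  Per-fold ROC AUCs are summarised as
mean ± sd (the headline), with the pooled-score AUC also reported.

The ensemble rule is a per-record minimum of two methods' normalized scores:
a compound is called active only when *both* methods agree, which removes
false positives that only one method makes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score, roc_curve

from .base import PredictionResult, make_result
from .featurize import FeatureTable
from .learners import MixedNB, PNNClassifier, ToxRandomForest
from .simsearch import TanimotoKNN, knn_predict

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    auc: float
    curve_points: np.ndarray  # (n_points, 2) columns fpr, tpr
    n_pos: int
    n_neg: int


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC curve and rank-based AUC (ties counted ½) of one score vector."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-D vectors")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one positive and one negative")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    curve = np.column_stack([fpr, tpr])
    return ROCResult(auc=auc, curve_points=curve, n_pos=n_pos, n_neg=n_neg)


# ---------------------------------------------------------------------------
# Min-score ensemble
# ---------------------------------------------------------------------------

def combine_min(
    scores_a: Sequence[PredictionResult],
    scores_b: Sequence[PredictionResult],
    threshold: float = 0.5,
) -> list[PredictionResult]:
    """Per-id minimum of two normalized score sets (``ensemble(min)``)."""
    by_id_b = {r.id: r for r in scores_b}
    ids_a = [r.id for r in scores_a]
    if set(ids_a) != set(by_id_b) or len(ids_a) != len(scores_b):
        only_a = sorted(set(ids_a) - set(by_id_b))
        only_b = sorted(set(by_id_b) - set(ids_a))
        raise ValueError(f"id mismatch between score sets: only_a={only_a!r} only_b={only_b!r}")
    out = []
    for ra in scores_a:
        rb = by_id_b[ra.id]
        out.append(
            make_result(ra.id, min(ra.score, rb.score), "ensemble(min)", threshold)
        )
    return out


class MinScoreEnsemble(BaseEstimator, ClassifierMixin):
    """Meta-estimator taking the element-wise minimum of component scores."""

    def __init__(self, estimators: Optional[list] = None, threshold: float = 0.5):
        self.estimators = estimators
        self.threshold = threshold

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MinScoreEnsemble":
        if not self.estimators or len(self.estimators) < 2:
            raise ValueError("MinScoreEnsemble needs at least two component estimators")
        self.classes_ = np.array([0, 1])
        self.fitted_ = [est.fit(X, y) for est in self.estimators]
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        scores = np.min([est.predict_proba(X)[:, 1] for est in self.fitted_], axis=0)
        return np.column_stack([1 - scores, scores])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)


# ---------------------------------------------------------------------------
# Stratified folds
# ---------------------------------------------------------------------------

@dataclass
class CVFoldPlan:
    n_folds: int
    assignments: np.ndarray  # per-record fold index
    seed: int
    stratified: bool = True

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.nonzero(self.assignments == fold)[0]
        train = np.nonzero(self.assignments != fold)[0]
        return train, test


def make_folds(labels: Sequence[int], n_folds: int = 13, seed: int = 0) -> CVFoldPlan:
    """Stratified fold plan: within-class shuffle then round-robin deal."""
    labels = np.asarray(labels, dtype=int)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    assignments = np.full(len(labels), -1, dtype=int)
    rng = np.random.default_rng(seed)
    for c in (0, 1):
        idx = np.nonzero(labels == c)[0]
        if len(idx) < n_folds:
            raise ValueError(
                f"class {c} has only {len(idx)} members, fewer than n_folds={n_folds}"
            )
        idx = rng.permutation(idx)
        assignments[idx] = np.arange(len(idx)) % n_folds
    return CVFoldPlan(n_folds=n_folds, assignments=assignments, seed=seed)


# ---------------------------------------------------------------------------
# Cross-validation driver
# ---------------------------------------------------------------------------

def build_estimator(method_spec: dict):
    """Instantiate the estimator named by a method config dictionary.

    Recognised ``algo`` values: ``knn`` (k), ``nb`` (alpha), ``rf``
    (split_criterion, data_fraction, n_trees, seed), ``pnn`` (sigma, seed)
    and ``ensemble_min`` (components: list of method specs).
    """
    spec = dict(method_spec)
    algo = spec.pop("algo", None)
    if algo == "knn":
        return TanimotoKNN(k=int(spec.get("k", 5)))
    if algo == "nb":
        return MixedNB(alpha=float(spec.get("alpha", 1.0)))
    if algo == "rf":
        return ToxRandomForest(
            n_trees=int(spec.get("n_trees", 1000)),
            split_criterion=spec.get("split_criterion", "gini"),
            data_fraction=float(spec.get("data_fraction", 0.8)),
            random_state=int(spec.get("seed", 0)),
        )
    if algo == "pnn":
        sigma = spec.get("sigma", "auto")
        return PNNClassifier(
            sigma=sigma if sigma == "auto" else float(sigma),
            random_state=int(spec.get("seed", 0)),
        )
    if algo == "ensemble_min":
        comps = spec.get("components")
        if not comps:
            raise ValueError("ensemble_min needs a 'components' list")
        return MinScoreEnsemble(estimators=[build_estimator(c) for c in comps])
    raise ValueError(f"unknown method algo {algo!r}")


@dataclass
class CVResult:
    fold_aucs: list  # float or None (fold missing a class)
    mean_auc: float
    sd_auc: float
    pooled_auc: float
    n_folds: int
    method_spec: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fold_aucs": self.fold_aucs,
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "pooled_auc": self.pooled_auc,
            "n_folds": self.n_folds,
            "method": self.method_spec,
        }


def cross_validate(
    table: FeatureTable, method_spec: dict, plan: CVFoldPlan
) -> CVResult:
    """Train on each fold's complement, score the fold, report per-fold AUC.

    A fold whose test part lacks one class has no defined AUC; it is recorded
    as ``None`` and excluded from the mean with a warning.
    """
    if table.labels is None:
        raise ValueError("cross-validation needs a labeled table")
    y = table.labels
    fold_aucs: list = []
    pooled_scores = np.empty(len(y))
    for fold in range(plan.n_folds):
        train_idx, test_idx = plan.fold_indices(fold)
        est = build_estimator(method_spec)
        est.fit(table.X[train_idx], y[train_idx])
        scores = est.predict_proba(table.X[test_idx])[:, 1]
        pooled_scores[test_idx] = scores
        y_test = y[test_idx]
        if y_test.min() == y_test.max():
            logger.warning("fold %d lacks one class; AUC undefined, skipped", fold)
            fold_aucs.append(None)
            continue
        fold_aucs.append(roc_auc(scores, y_test).auc)
    valid = [a for a in fold_aucs if a is not None]
    if not valid:
        raise ValueError("no fold had both classes; cannot summarise AUC")
    return CVResult(
        fold_aucs=fold_aucs,
        mean_auc=float(np.mean(valid)),
        sd_auc=float(np.std(valid, ddof=1)) if len(valid) > 1 else 0.0,
        pooled_auc=roc_auc(pooled_scores, y).auc,
        n_folds=plan.n_folds,
        method_spec=dict(method_spec),
    )
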