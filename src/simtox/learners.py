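"""The three classifiers: Naïve Bayes, Random Forest and a probabilistic
neural network (PNN), each exposed as a scikit-learn style estimator plus a
functional ``train_* / predict`` layer operating on :class:`FeatureTable`.

* :class:`MixedNB` — naïve Bayes with Bernoulli likelihoods (Laplace α=1)
  on binary fingerprint bits and class-conditional Gaussians (variance
  floor 1e-9) on continuous descriptor columns.
* :class:`ToxRandomForest` — 1000-tree forest with bootstrap samples of
  ``data_fraction · n`` rows, √p candidate attributes per split and trees
  grown to purity; ``gini`` splits are delegated to scikit-learn, the
  ``info_gain_ratio`` criterion (Quinlan form: information gain divided by
  split entropy) is implemented in-house since scikit-learn lacks it.  The
  prediction score is the fraction of trees voting active (equivalently the
  mean leaf active-fraction; identical when leaves are pure).
* :class:`PNNClassifier` — classic Specht formulation: Gaussian kernels
  centred on every training point, class-averaged densities, score =
  active density / (active + inactive density).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import joblib
import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .base import PredictionResult, make_result
from .featurize import FeatureTable

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


def _check_two_classes(y: np.ndarray, algo: str) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError(f"{algo} requires both classes in the training set")


# ---------------------------------------------------------------------------
# Naïve Bayes
# ---------------------------------------------------------------------------

class MixedNB(BaseEstimator, ClassifierMixin):
    """Naïve Bayes over mixed binary + continuous feature tables.

    Binary columns (all observed values in {0,1}) get per-class Bernoulli
    likelihoods with Laplace smoothing ``alpha``; the remaining columns get
    class-conditional Gaussians with a variance floor.  Class priors come
    from training frequencies.
    """

    def __init__(self, alpha: float = 1.0, var_floor: float = 1e-9):
        self.alpha = alpha
        self.var_floor = var_floor

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MixedNB":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        _check_two_classes(y, "NB")
        self.classes_ = np.array([0, 1])
        self.binary_mask_ = np.array(
            [np.isin(col, (0.0, 1.0)).all() for col in X.T], dtype=bool
        )
        self.class_log_prior_ = np.log(
            np.array([(y == c).sum() for c in self.classes_]) / len(y)
        )
        Xb = X[:, self.binary_mask_]
        Xg = X[:, ~self.binary_mask_]
        self.bern_logp_ = np.empty((2, Xb.shape[1]))
        self.bern_log1mp_ = np.empty((2, Xb.shape[1]))
        self.gauss_mean_ = np.empty((2, Xg.shape[1]))
        self.gauss_var_ = np.empty((2, Xg.shape[1]))
        for ci, c in enumerate(self.classes_):
            rows = y == c
            n_c = rows.sum()
            p = (Xb[rows].sum(axis=0) + self.alpha) / (n_c + 2 * self.alpha)
            self.bern_logp_[ci] = np.log(p)
            self.bern_log1mp_[ci] = np.log1p(-p)
            if Xg.shape[1]:
                self.gauss_mean_[ci] = Xg[rows].mean(axis=0)
                self.gauss_var_[ci] = np.maximum(Xg[rows].var(axis=0), self.var_floor)
        return self

    def _joint_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "class_log_prior_")
        X = np.asarray(X, dtype=float)
        Xb = X[:, self.binary_mask_]
        Xg = X[:, ~self.binary_mask_]
        jll = np.tile(self.class_log_prior_, (X.shape[0], 1))
        for ci in range(2):
            jll[:, ci] += Xb @ self.bern_logp_[ci] + (1 - Xb) @ self.bern_log1mp_[ci]
            if Xg.shape[1]:
                jll[:, ci] += (
                    -0.5 * np.log(2 * np.pi * self.gauss_var_[ci])
                    - 0.5 * (Xg - self.gauss_mean_[ci]) ** 2 / self.gauss_var_[ci]
                ).sum(axis=1)
        return jll

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        jll = self._joint_log_likelihood(X)
        return np.exp(jll - logsumexp(jll, axis=1, keepdims=True))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# Random forest — gain-ratio trees (in-house) and gini (scikit-learn)
# ---------------------------------------------------------------------------

def _entropy(counts: np.ndarray) -> np.ndarray:
    """Shannon entropy (nats) of count rows [..., n_classes]."""
    total = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, counts / np.maximum(total, 1), 0.0)
        h = np.where(p > 0, -p * np.log(p), 0.0)
    return h.sum(axis=-1)


def _best_gain_ratio_split(x: np.ndarray, y: np.ndarray):
    """Best (gain_ratio, threshold) for one numeric feature, or None."""
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    # candidate cuts between distinct consecutive values
    diff = np.nonzero(xs[1:] > xs[:-1])[0]
    if diff.size == 0:
        return None
    n = len(y)
    cum_pos = np.cumsum(ys)
    n_pos = cum_pos[-1]
    n_left = diff + 1
    left_pos = cum_pos[diff]
    left = np.stack([n_left - left_pos, left_pos], axis=1)
    right = np.stack([(n - n_left) - (n_pos - left_pos), n_pos - left_pos], axis=1)
    parent_h = _entropy(np.array([n - n_pos, n_pos], dtype=float))
    w_left = n_left / n
    child_h = w_left * _entropy(left.astype(float)) + (1 - w_left) * _entropy(
        right.astype(float)
    )
    gain = parent_h - child_h
    split_h = _entropy(np.stack([n_left, n - n_left], axis=1).astype(float))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(split_h > 0, gain / np.maximum(split_h, 1e-300), -np.inf)
    best = int(np.argmax(ratio))
    if not np.isfinite(ratio[best]) or gain[best] <= 1e-12:
        return None
    thr = 0.5 * (xs[diff[best]] + xs[diff[best] + 1])
    return float(ratio[best]), float(thr)


class _GainRatioTree:
    """One decision tree with Quinlan gain-ratio splits, grown to purity."""

    def __init__(self, max_features: int, rng: np.random.Generator):
        self.max_features = max_features
        self.rng = rng
        self.nodes: list[tuple] = []  # (feature, thr, left, right) or (-1, frac, -1, -1)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_GainRatioTree":
        stack = [(np.arange(len(y)), self._new_node())]
        while stack:
            idx, node_id = stack.pop()
            ysub = y[idx]
            frac = ysub.mean()
            if frac in (0.0, 1.0) or len(idx) < 2:
                self.nodes[node_id] = (-1, frac, -1, -1)
                continue
            feats = self.rng.choice(X.shape[1], size=self.max_features, replace=False)
            best = None
            for f in feats:
                res = _best_gain_ratio_split(X[idx, f], ysub)
                if res is not None and (best is None or res[0] > best[0]):
                    best = (res[0], int(f), res[1])
            if best is None:
                self.nodes[node_id] = (-1, frac, -1, -1)
                continue
            _, f, thr = best
            mask = X[idx, f] <= thr
            left, right = self._new_node(), self._new_node()
            self.nodes[node_id] = (f, thr, left, right)
            stack.append((idx[mask], left))
            stack.append((idx[~mask], right))
        return self

    def _new_node(self) -> int:
        self.nodes.append((-1, 0.0, -1, -1))
        return len(self.nodes) - 1

    def predict_frac(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            node = 0
            while True:
                f, thr, left, right = self.nodes[node]
                if f < 0:
                    out[i] = thr
                    break
                node = left if row[f] <= thr else right
        return out


class ToxRandomForest(BaseEstimator, ClassifierMixin):
    """Random forest with the configuration used for toxicity endpoints.

    Parameters
    ----------
    n_trees : int, default 1000
    split_criterion : {"gini", "info_gain_ratio"}, default "gini"
    data_fraction : float, default 0.8
        Bootstrap sample size per tree as a fraction of n (with replacement).
    random_state : int, optional
    """

    def __init__(
        self,
        n_trees: int = 1000,
        split_criterion: str = "gini",
        data_fraction: float = 0.8,
        random_state: Optional[int] = None,
    ):
        self.n_trees = n_trees
        self.split_criterion = split_criterion
        self.data_fraction = data_fraction
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ToxRandomForest":
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0 < self.data_fraction <= 1:
            raise ValueError("data_fraction must be in (0, 1]")
        if self.split_criterion not in ("gini", "info_gain_ratio"):
            raise ValueError(f"unknown split criterion {self.split_criterion!r}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        _check_two_classes(y, "RF")
        self.classes_ = np.array([0, 1])
        if self.split_criterion == "gini":
            self.impl_ = RandomForestClassifier(
                n_estimators=self.n_trees,
                criterion="gini",
                max_features="sqrt",
                bootstrap=True,
                max_samples=self.data_fraction if self.data_fraction < 1 else None,
                min_samples_leaf=1,
                random_state=self.random_state,
                n_jobs=1,
            ).fit(X, y)
        else:
            rng = np.random.default_rng(self.random_state)
            n = len(y)
            n_boot = max(1, int(np.ceil(self.data_fraction * n)))
            max_feats = max(1, int(np.ceil(np.sqrt(X.shape[1]))))
            self.trees_ = []
            for _ in range(self.n_trees):
                rows = rng.integers(0, n, size=n_boot)
                tree = _GainRatioTree(max_feats, rng).fit(X[rows], y[rows])
                self.trees_.append(tree)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "classes_")
        X = np.asarray(X, dtype=float)
        if self.split_criterion == "gini":
            proba = self.impl_.predict_proba(X)
            if proba.shape[1] == 1:  # defensive; both classes enforced in fit
                proba = np.column_stack([1 - proba, proba])
            return proba
        frac = np.mean([t.predict_frac(X) for t in self.trees_], axis=0)
        return np.column_stack([1 - frac, frac])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# Probabilistic neural network
# ---------------------------------------------------------------------------

class PNNClassifier(BaseEstimator, ClassifierMixin):
    """Gaussian-kernel probabilistic neural network (Specht).

    Every training point is a kernel centre; the per-class density is the
    *average* of ``exp(−‖x−c‖²/(2σ²))`` over that class's centres (the
    average makes the density insensitive to class size), and the prediction
    score is ``active density / (active + inactive density)``.  Densities
    are evaluated in log space so that very small bandwidths degrade
    gracefully to nearest-centre classification instead of underflowing.

    ``sigma="auto"`` sets the bandwidth to the median Euclidean distance of
    500 subsampled training pairs.
    """

    def __init__(
        self,
        sigma: Union[float, str] = "auto",
        random_state: Optional[int] = None,
        n_sigma_pairs: int = 500,
    ):
        self.sigma = sigma
        self.random_state = random_state
        self.n_sigma_pairs = n_sigma_pairs

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PNNClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        _check_two_classes(y, "PNN")
        if not (self.sigma == "auto" or (np.isreal(self.sigma) and self.sigma > 0)):
            raise ValueError("sigma must be positive or 'auto'")
        self.classes_ = np.array([0, 1])
        self.centers_ = [X[y == 0], X[y == 1]]
        if self.sigma == "auto":
            rng = np.random.default_rng(self.random_state)
            n = X.shape[0]
            i = rng.integers(0, n, size=self.n_sigma_pairs)
            j = rng.integers(0, n, size=self.n_sigma_pairs)
            d = np.linalg.norm(X[i] - X[j], axis=1)
            d = d[d > 0]
            self.sigma_ = float(np.median(d)) if d.size else 1.0
        else:
            self.sigma_ = float(self.sigma)
        return self

    def _log_density(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "sigma_")
        X = np.asarray(X, dtype=float)
        logd = np.empty((X.shape[0], 2))
        for ci in range(2):
            d2 = cdist(X, self.centers_[ci], metric="sqeuclidean")
            logd[:, ci] = logsumexp(-d2 / (2 * self.sigma_**2), axis=1) - np.log(
                self.centers_[ci].shape[0]
            )
        return logd

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logd = self._log_density(X)
        return np.exp(logd - logsumexp(logd, axis=1, keepdims=True))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# FeatureTable-level training / prediction / serialization
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A fitted classifier bound to its feature columns and provenance."""

    algorithm: str  # NB | RF | PNN | KNN
    hyperparameters: dict
    estimator: object
    feature_columns: list[str]
    training_summary: dict = field(default_factory=dict)
    format_version: int = MODEL_FORMAT_VERSION


def _summary(table: FeatureTable) -> dict:
    y = table.labels
    return {
        "n": table.n_records,
        "n_active": int(y.sum()),
        "n_inactive": int((1 - y).sum()),
        "n_features": len(table.columns),
    }


def _require_labels(table: FeatureTable) -> None:
    if table.labels is None:
        raise ValueError("training table must carry binary labels")


def train_nb(table: FeatureTable, alpha: float = 1.0) -> TrainedModel:
    _require_labels(table)
    est = MixedNB(alpha=alpha).fit(table.X, table.labels)
    return TrainedModel("NB", {"alpha": alpha}, est, list(table.columns), _summary(table))


def train_rf(
    table: FeatureTable,
    split_criterion: str = "gini",
    data_fraction: float = 0.8,
    n_trees: int = 1000,
    seed: int = 0,
) -> TrainedModel:
    _require_labels(table)
    est = ToxRandomForest(
        n_trees=n_trees,
        split_criterion=split_criterion,
        data_fraction=data_fraction,
        random_state=seed,
    ).fit(table.X, table.labels)
    hp = {
        "split_criterion": split_criterion,
        "data_fraction": data_fraction,
        "n_trees": n_trees,
        "seed": seed,
    }
    return TrainedModel("RF", hp, est, list(table.columns), _summary(table))


def train_pnn(
    table: FeatureTable, sigma: Union[float, str] = "auto", seed: int = 0
) -> TrainedModel:
    _require_labels(table)
    est = PNNClassifier(sigma=sigma, random_state=seed).fit(table.X, table.labels)
    return TrainedModel(
        "PNN", {"sigma": sigma, "seed": seed}, est, list(table.columns), _summary(table)
    )


def predict(
    model: TrainedModel, queries: FeatureTable, threshold: float = 0.5
) -> list[PredictionResult]:
    """Score a query table with a trained model.

    Query columns must match the training columns exactly (names and order);
    a mismatch is fatal and reports the difference.
    """
    if list(queries.columns) != list(model.feature_columns):
        missing = set(model.feature_columns) - set(queries.columns)
        extra = set(queries.columns) - set(model.feature_columns)
        raise ValueError(
            "query columns do not match training columns: "
            f"missing={sorted(missing)!r} extra={sorted(extra)!r} "
            f"(order must match too)"
        )
    scores = model.estimator.predict_proba(queries.X)[:, 1]
    return [
        make_result(rec_id, s, method=model.algorithm, threshold=threshold)
        for rec_id, s in zip(queries.ids, scores)
    ]


def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump(
        {
            "format_version": model.format_version,
            "algorithm": model.algorithm,
            "hyperparameters": model.hyperparameters,
            "feature_columns": model.feature_columns,
            "training_summary": model.training_summary,
            "estimator": model.estimator,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    blob = joblib.load(path)
    if blob.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {blob.get('format_version')}")
    return TrainedModel(
        algorithm=blob["algorithm"],
        hyperparameters=blob["hyperparameters"],
        estimator=blob["estimator"],
        feature_columns=blob["feature_columns"],
        training_summary=blob["training_summary"],
    )
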