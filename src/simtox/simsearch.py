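"""Tanimoto similarity search and similarity-weighted kNN scoring.

A query compound is compared against every training compound by the Tanimoto
coefficient of their binary fingerprints and the top ``k`` most similar
records become its nearest neighbours (NNs).  The prediction score depends on
the composition of the neighbour set:

* all NNs active:    ``score1 = (Σ T_n) / k``
* all NNs inactive:  ``score2 = 1 − score1``
* mixed:             ``score3 = (Σ T_n)/k_a + (1 − (Σ T_m)/k_in)``

where ``T_n`` runs over active and ``T_m`` over inactive neighbour
similarities, ``k_a + k_in = k``.  ``score3`` lives on [0, 2]; the normalized
prediction score (raw/2 on the mixed branch, raw otherwise) is in [0, 1] and
is what downstream ROC analysis and ensembling consume.  The raw value is
always retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .base import PredictionResult, make_result
from .featurize import FeatureTable, FingerprintVector

logger = logging.getLogger(__name__)


@dataclass
class NeighborList:
    """The k nearest training records for one query, sorted by T descending."""

    query_id: str
    neighbors: list[tuple[str, float, int]]  # (train_id, tanimoto, label)

    def __post_init__(self) -> None:
        ts = [t for _, t, _ in self.neighbors]
        if any(ts[i] < ts[i + 1] for i in range(len(ts) - 1)):
            raise ValueError("neighbors must be sorted by T descending")
        if any(lbl not in (0, 1) for _, _, lbl in self.neighbors):
            raise ValueError("neighbor labels must be binary")

    @property
    def k(self) -> int:
        return len(self.neighbors)

    @property
    def k_a(self) -> int:
        return sum(lbl for _, _, lbl in self.neighbors)

    @property
    def k_in(self) -> int:
        return self.k - self.k_a


@dataclass
class KnnScore:
    raw: float
    normalized: float
    branch: str  # all_active | all_inactive | mixed


def tanimoto(a: FingerprintVector | np.ndarray, b: FingerprintVector | np.ndarray) -> float:
    """Tanimoto coefficient |a∧b| / |a∨b| of two binary fingerprints."""
    if isinstance(a, FingerprintVector) and isinstance(b, FingerprintVector):
        if a.fp_type != b.fp_type:
            raise ValueError(f"fingerprint type mismatch: {a.fp_type} vs {b.fp_type}")
        va, vb = a.bits, b.bits
    else:
        va = a.bits if isinstance(a, FingerprintVector) else np.asarray(a)
        vb = b.bits if isinstance(b, FingerprintVector) else np.asarray(b)
    if va.shape != vb.shape:
        raise ValueError(f"fingerprint length mismatch: {va.shape} vs {vb.shape}")
    va = va.astype(bool)
    vb = vb.astype(bool)
    union = np.count_nonzero(va | vb)
    if union == 0:
        warnings.warn("Tanimoto of two all-zero fingerprints defined as 0", stacklevel=2)
        return 0.0
    return np.count_nonzero(va & vb) / union


def bulk_tanimoto(Q: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto matrix (queries × training) for binary matrices."""
    Q = np.asarray(Q, dtype=float)
    T = np.asarray(T, dtype=float)
    if Q.shape[1] != T.shape[1]:
        raise ValueError("fingerprint length mismatch between query and training")
    inter = Q @ T.T
    union = Q.sum(axis=1)[:, None] + T.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    if (union == 0).any():
        warnings.warn("Tanimoto of all-zero fingerprint pair defined as 0", stacklevel=2)
    return sim


def _topk_indices(sims: np.ndarray, k: int) -> np.ndarray:
    # exact top-k; ties at the k-th position broken by ascending row index
    order = np.lexsort((np.arange(sims.size), -sims))
    return order[:k]


def find_neighbors(
    query: FingerprintVector | np.ndarray,
    train: FeatureTable,
    k: int,
    query_id: str = "query",
) -> NeighborList:
    """Exact top-k Tanimoto neighbours of one query in a labeled table."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if train.labels is None:
        raise ValueError("training table must carry binary labels")
    fp = train.fingerprint_matrix()
    if fp.shape[0] == 0:
        raise ValueError("training table is empty")
    if k > fp.shape[0]:
        logger.warning("k=%d exceeds training size %d; using all rows", k, fp.shape[0])
        k = fp.shape[0]
    q = query.bits if isinstance(query, FingerprintVector) else np.asarray(query)
    sims = bulk_tanimoto(q[None, :], fp)[0]
    idx = _topk_indices(sims, k)
    return NeighborList(
        query_id=query_id,
        neighbors=[(train.ids[i], float(sims[i]), int(train.labels[i])) for i in idx],
    )


def knn_score(nl: NeighborList) -> KnnScore:
    """Similarity-weighted kNN score of one neighbour list."""
    if nl.k == 0:
        raise ValueError("empty neighbor list")
    ts = np.array([t for _, t, _ in nl.neighbors])
    labels = np.array([lbl for _, _, lbl in nl.neighbors])
    if labels.all():
        raw = ts.mean()                      # score1
        return KnnScore(raw=float(raw), normalized=float(raw), branch="all_active")
    if not labels.any():
        raw = 1.0 - ts.mean()                # score2
        return KnnScore(raw=float(raw), normalized=float(raw), branch="all_inactive")
    raw = ts[labels == 1].mean() + (1.0 - ts[labels == 0].mean())  # score3
    return KnnScore(raw=float(raw), normalized=float(raw) / 2.0, branch="mixed")


class TanimotoKNN(BaseEstimator, ClassifierMixin):
    """Similarity-weighted k-nearest-neighbour classifier on binary fingerprints.

    Parameters
    ----------
    k : int, default 5
        Number of nearest neighbours (3, 5 and 7 are the standard settings).
    threshold : float, default 0.5
        Hard-class cutoff on the normalized score.
    """

    def __init__(self, k: int = 5, threshold: float = 0.5):
        self.k = k
        self.threshold = threshold

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TanimotoKNN":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X and y misaligned")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary")
        if not np.isin(X, (0, 1)).all():
            raise ValueError("TanimotoKNN requires a binary fingerprint matrix")
        self.X_ = X
        self.y_ = y
        self.classes_ = np.array([0, 1])
        return self

    def _scores(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[str]]:
        check_is_fitted(self, "X_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n_train = self.X_.shape[0]
        k = min(self.k, n_train)
        if self.k > n_train:
            logger.warning("k=%d exceeds training size %d; using all rows", self.k, n_train)
        sims = bulk_tanimoto(X, self.X_)
        raw = np.empty(X.shape[0])
        norm = np.empty(X.shape[0])
        branches: list[str] = []
        for i in range(X.shape[0]):
            idx = _topk_indices(sims[i], k)
            nl = NeighborList(
                query_id=str(i),
                neighbors=[(str(j), float(sims[i, j]), int(self.y_[j])) for j in idx],
            )
            s = knn_score(nl)
            raw[i], norm[i] = s.raw, s.normalized
            branches.append(s.branch)
        return raw, norm, branches

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        _, norm, _ = self._scores(X)
        return np.column_stack([1.0 - norm, norm])

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)


def knn_predict(
    queries: FeatureTable,
    train: FeatureTable,
    k: int = 5,
    threshold: float = 0.5,
) -> list[PredictionResult]:
    """Score every query against a labeled training table.

    The query and training tables must share the fingerprint type; the
    normalized score is the prediction score and the hard class is
    ``score >= threshold``.
    """
    if train.labels is None:
        raise ValueError("training table must carry binary labels")
    qt = queries.fingerprint_type()
    tt = train.fingerprint_type()
    if qt != tt:
        raise ValueError(f"fingerprint type mismatch: query {qt} vs train {tt}")
    if queries.n_records == 0:
        return []
    model = TanimotoKNN(k=k, threshold=threshold).fit(
        train.fingerprint_matrix(), train.labels
    )
    _, norm, _ = model._scores(queries.fingerprint_matrix())
    return [
        make_result(rec_id, s, method=f"{k}NN", threshold=threshold)
        for rec_id, s in zip(queries.ids, norm)
    ]


def knn_details(
    queries: FeatureTable, train: FeatureTable, k: int = 5, threshold: float = 0.5
) -> list[dict]:
    """Full per-query output (raw, normalized, branch, neighbours) for export."""
    out = []
    for i in range(queries.n_records):
        nl = find_neighbors(
            queries.fingerprint_matrix()[i], train, k, query_id=queries.ids[i]
        )
        s = knn_score(nl)
        out.append(
            {
                "id": queries.ids[i],
                "raw_score": s.raw,
                "normalized_score": s.normalized,
                "branch": s.branch,
                "predicted_class": int(s.normalized >= threshold),
                "neighbor_ids": ";".join(nid for nid, _, _ in nl.neighbors),
                "neighbor_T": ";".join(f"{t:.6f}" for _, t, _ in nl.neighbors),
            }
        )
    return out
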