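"""Historical-record matching: exact attribute match, else k-means +
Euclidean nearest-tuple search.

A new user is first cross-referenced against the cohort on a configurable
attribute list (age, nutrient intake frequencies, supplement usage,
hereditary factors by default). When no exact match exists, the encoded
cohort is clustered with k-means and the query is matched to the exact
Euclidean nearest record inside its nearest centroid's cluster (with a
logged global fallback for empty clusters).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import kmeans_plusplus

from .cohort import CohortTable
from .errors import ClusteringError, ContractError
from .preprocessing import EncodedMatrix

__all__ = [
    "MatchResult",
    "KMeansModel",
    "DEFAULT_MATCH_FIELDS",
    "default_k",
    "find_exact_match",
    "kmeans_fit",
    "nearest_tuple",
    "KMeansMatcher",
]

logger = logging.getLogger(__name__)

DEFAULT_MATCH_FIELDS = ("age", "supplement_used", "hereditary",
                        "protein_freq", "iron_freq", "omega_freq")


def default_k(n: int) -> int:
    """``ceil(sqrt(n/2))`` capped at 10 — a conventional cluster-count rule."""
    return max(1, min(10, math.ceil(math.sqrt(n / 2)))) if n else 1


@dataclass
class MatchResult:
    matched_user_id: str
    match_type: str  # "exact" | "cluster_nearest"
    distance: float
    cluster_id: int | None = None
    row_index: int | None = None


@dataclass
class KMeansModel:
    centroids: np.ndarray
    assignments: np.ndarray
    k: int
    seed: int
    inertia: float
    inertia_history: list = field(default_factory=list)
    n_iter: int = 0


def find_exact_match(query: Mapping, cohort: CohortTable | pd.DataFrame,
                     fields: Sequence[str] = DEFAULT_MATCH_FIELDS) -> MatchResult | None:
    """First cohort record equal to the query on every listed field.

    Ties broken by lowest row index; returns None when nothing matches.
    """
    df = cohort.records if isinstance(cohort, CohortTable) else cohort
    if not fields:
        raise ContractError("fields must be non-empty")
    missing = [f for f in fields if f not in df.columns or f not in query]
    if missing:
        raise ContractError(f"unknown match fields: {missing}")
    if df.empty:
        return None
    mask = np.ones(len(df), dtype=bool)
    for f in fields:
        mask &= (df[f] == query[f]).to_numpy()
    hits = np.flatnonzero(mask)
    if hits.size == 0:
        return None
    row = int(hits[0])
    return MatchResult(matched_user_id=str(df.iloc[row]["user_id"]),
                       match_type="exact", distance=0.0, row_index=row)


def kmeans_fit(matrix: EncodedMatrix | np.ndarray, k: int, seed: int = 0,
               max_iter: int = 300, tol: float = 1e-6) -> KMeansModel:
    """Lloyd's algorithm from a seeded k-means++ initialisation.

    Stops when the maximum centroid shift falls below ``tol`` or after
    ``max_iter`` sweeps. The recorded inertia history is non-increasing.
    """
    X = matrix.values if isinstance(matrix, EncodedMatrix) else np.asarray(matrix, dtype=float)
    n = len(X)
    if k < 1:
        raise ClusteringError("k must be >= 1")
    if n < k:
        raise ClusteringError(f"need at least k={k} rows, got {n}")

    centroids, _ = kmeans_plusplus(X, n_clusters=k, random_state=seed)
    history = []
    labels = np.zeros(n, dtype=int)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        history.append(float(d2[np.arange(n), labels].sum()))
        new_centroids = centroids.copy()
        for j in range(k):
            members = X[labels == j]
            if len(members):
                new_centroids[j] = members.mean(axis=0)
        shift = float(np.abs(new_centroids - centroids).max())
        centroids = new_centroids
        if shift < tol:
            break
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(n), labels].sum())
    history.append(inertia)
    return KMeansModel(centroids=centroids, assignments=labels, k=k, seed=seed,
                       inertia=inertia, inertia_history=history, n_iter=n_iter)


def nearest_tuple(query: np.ndarray, model: KMeansModel,
                  matrix: EncodedMatrix | np.ndarray,
                  user_ids: Sequence[str] | None = None) -> MatchResult:
    """Closest record by Euclidean distance, accelerated by the clustering.

    Clusters are visited in order of centroid distance; a cluster is
    skipped when the triangle-inequality bound ``d(q, centroid) - radius``
    proves it cannot beat the best record found so far. The result equals
    the global brute-force nearest neighbour. An empty nearest cluster is
    logged and skipped.
    """
    X = matrix.values if isinstance(matrix, EncodedMatrix) else np.asarray(matrix, dtype=float)
    q = np.asarray(query, dtype=float)
    if q.shape != (X.shape[1],):
        raise ContractError(f"query shape {q.shape} incompatible with matrix {X.shape}")
    if len(X) == 0:
        raise ContractError("matrix is empty")

    centroid_d = np.sqrt(((model.centroids - q) ** 2).sum(axis=1))
    order = np.argsort(centroid_d)
    # per-cluster radius: furthest member from its centroid
    radii = np.zeros(model.k)
    for j in range(model.k):
        members = np.flatnonzero(model.assignments == j)
        if members.size:
            radii[j] = np.sqrt(((X[members] - model.centroids[j]) ** 2).sum(axis=1)).max()

    best_idx, best_d, best_cluster = -1, np.inf, int(order[0])
    for j in order:
        members = np.flatnonzero(model.assignments == j)
        if members.size == 0:
            if j == order[0]:
                logger.warning("nearest cluster %d is empty; widening search", j)
            continue
        if centroid_d[j] - radii[j] > best_d:
            continue
        dists = np.sqrt(((X[members] - q) ** 2).sum(axis=1))
        local = int(dists.argmin())
        if dists[local] < best_d:
            best_d, best_idx, best_cluster = float(dists[local]), int(members[local]), int(j)
    uid = str(user_ids[best_idx]) if user_ids is not None else str(best_idx)
    return MatchResult(matched_user_id=uid, match_type="cluster_nearest",
                       distance=best_d, cluster_id=best_cluster, row_index=best_idx)


class KMeansMatcher:
    """Estimator wrapper: fit k-means on a cohort matrix, query nearest tuples."""

    def __init__(self, k: int | None = None, seed: int = 0,
                 max_iter: int = 300, tol: float = 1e-6):
        self.k = k
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol

    def get_params(self, deep: bool = True) -> dict:
        return {"k": self.k, "seed": self.seed, "max_iter": self.max_iter, "tol": self.tol}

    def set_params(self, **params) -> "KMeansMatcher":
        for key, v in params.items():
            if not hasattr(self, key):
                raise ContractError(f"unknown parameter {key!r}")
            setattr(self, key, v)
        return self

    def fit(self, matrix: EncodedMatrix | np.ndarray,
            user_ids: Sequence[str] | None = None) -> "KMeansMatcher":
        X = matrix.values if isinstance(matrix, EncodedMatrix) else np.asarray(matrix, dtype=float)
        k = self.k if self.k is not None else default_k(len(X))
        self.model_ = kmeans_fit(X, k=k, seed=self.seed, max_iter=self.max_iter, tol=self.tol)
        self.matrix_ = X
        self.user_ids_ = list(user_ids) if user_ids is not None else None
        return self

    def query(self, query: np.ndarray) -> MatchResult:
        return nearest_tuple(query, self.model_, self.matrix_, self.user_ids_)
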