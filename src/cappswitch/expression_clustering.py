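"""Expression clustering of TSS across growth conditions.

The transform mirrors standard practice for grouping expression profiles by
shape rather than magnitude: log2 with a pseudocount, per-row median
centering, unit sum-of-squares scaling, then K-means under the city-block
(L1) metric with component-wise median centroid updates — the median being
the L1-optimal centroid, just as the mean is for squared Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted


def normalize_expression(matrix: pd.DataFrame, pseudocount: float = 1.0
                         ) -> tuple[pd.DataFrame, list[str]]:
    """log2(x + pseudocount), per-row median centering, unit sum-of-squares.

    Rows that are constant across conditions are all-zero after centering,
    carry no profile shape, and are dropped; their ids are returned alongside
    the normalized matrix.
    """
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression values must be >= 0")
    x = np.log2(matrix.to_numpy(dtype=float) + pseudocount)
    x = x - np.median(x, axis=1, keepdims=True)
    norms = np.sqrt((x ** 2).sum(axis=1))
    keep = norms > 0
    dropped = [str(i) for i in matrix.index[~keep]]
    x = x[keep] / norms[keep, None]
    return pd.DataFrame(x, index=matrix.index[keep], columns=matrix.columns), dropped


class CityBlockKMeans(BaseEstimator, ClusterMixin):
    """K-means under the city-block (L1, Manhattan) metric.

    Lloyd-style alternation: points are assigned to the nearest centroid by
    L1 distance and centroids are updated to the component-wise median of
    their members (the exact L1 minimizer). Clusters emptied by an update
    are re-seeded from the point farthest from its current centroid. The
    best of ``n_init`` random restarts by total L1 objective is kept.

    Parameters
    ----------
    n_clusters : number of clusters k.
    n_init : independent random restarts.
    max_iter : Lloyd iteration cap per restart.
    random_state : seed; identical seeds give identical results.

    Attributes (after ``fit``)
    --------------------------
    cluster_centers_ : (k, p) centroid matrix.
    labels_ : per-row cluster assignment, dense ids 0..k-1.
    inertia_ : total city-block distance of rows to their centroids.
    objective_path_ : per-iteration objective of the winning restart
        (non-increasing).
    n_iter_ : iterations used by the winning restart.
    """

    def __init__(self, n_clusters: int = 24, n_init: int = 10,
                 max_iter: int = 300, random_state: int | None = None):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n = X.shape[0]
        k = self.n_clusters
        if k <= 0:
            raise ValueError("n_clusters must be positive")
        if k > n:
            raise ValueError(f"n_clusters={k} exceeds number of rows {n}")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_init):
            labels, centers, path = self._lloyd(X, rng)
            if best is None or path[-1] < best[2][-1]:
                best = (labels, centers, path)
        self.labels_, self.cluster_centers_, self.objective_path_ = best
        self.inertia_ = float(self.objective_path_[-1])
        self.n_iter_ = len(self.objective_path_)
        self.n_features_in_ = X.shape[1]
        return self

    def _lloyd(self, X, rng):
        n, k = X.shape[0], self.n_clusters
        centers = X[rng.choice(n, size=k, replace=False)].copy()
        labels = None
        path = []
        for _ in range(self.max_iter):
            d = cdist(X, centers, metric="cityblock")
            new_labels = d.argmin(axis=1)
            # re-seed empty clusters from the farthest point; repeat because a
            # re-seed can empty another cluster (duplicate rows make clusters
            # unavoidably empty when k exceeds the number of distinct rows)
            for _ in range(k):
                empty = [c for c in range(k) if not (new_labels == c).any()]
                if not empty:
                    break
                c = empty[0]
                far = d[np.arange(n), new_labels].argmax()
                centers[c] = X[far]
                d[:, c] = cdist(X, centers[c:c + 1], metric="cityblock")[:, 0]
                new_labels = d.argmin(axis=1)
            obj = float(d[np.arange(n), new_labels].sum())
            path.append(obj)
            if labels is not None and (new_labels == labels).all():
                break
            labels = new_labels
            for c in range(k):
                members = labels == c
                if members.any():
                    centers[c] = np.median(X[members], axis=0)
        # final objective with converged centers
        d = cdist(X, centers, metric="cityblock")
        labels = d.argmin(axis=1)
        path.append(float(d[np.arange(n), labels].sum()))
        return labels, centers, path

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = np.asarray(X, dtype=float)
        return cdist(X, self.cluster_centers_, metric="cityblock").argmin(axis=1)

    def transform(self, X):
        check_is_fitted(self, "cluster_centers_")
        return cdist(np.asarray(X, dtype=float), self.cluster_centers_,
                     metric="cityblock")


@dataclass
class ClusterResult:
    k: int
    assignments: dict[str, int]
    centroids: np.ndarray
    objective: float
    objective_path: list[float]
    seed: int | None
    n_restarts: int


def kmeans_cityblock(matrix: pd.DataFrame, k: int = 24,
                     seed: int | None = None, n_restarts: int = 10,
                     max_iter: int = 300) -> ClusterResult:
    """Cluster a normalized expression matrix; thin wrapper over
    :class:`CityBlockKMeans` operating on a row-id-indexed DataFrame.

    Rows are processed in canonically sorted index order so the result does
    not depend on input row order.
    """
    matrix = matrix.sort_index()
    est = CityBlockKMeans(n_clusters=k, n_init=n_restarts, max_iter=max_iter,
                          random_state=seed).fit(matrix.to_numpy(dtype=float))
    assignments = {str(idx): int(lbl)
                   for idx, lbl in zip(matrix.index, est.labels_)}
    return ClusterResult(k=k, assignments=assignments,
                         centroids=est.cluster_centers_,
                         objective=est.inertia_,
                         objective_path=[float(v) for v in est.objective_path_],
                         seed=seed, n_restarts=n_restarts)


def cluster_report(result: ClusterResult, matrix: pd.DataFrame) -> pd.DataFrame:
    """Heatmap-ready member table: one row per TSS, ordered by cluster then
    by each member's L1 contribution to the objective."""
    matrix = matrix.sort_index()
    rows = []
    for rid, cl in result.assignments.items():
        profile = matrix.loc[rid].to_numpy(dtype=float)
        contrib = float(np.abs(profile - result.centroids[cl]).sum())
        row = {"tss_id": rid, "cluster": cl, "l1_to_centroid": round(contrib, 6)}
        for col in matrix.columns:
            row[str(col)] = round(float(matrix.loc[rid, col]), 6)
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(["cluster", "l1_to_centroid", "tss_id"],
                          kind="stable").reset_index(drop=True)
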