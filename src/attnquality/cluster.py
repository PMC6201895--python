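"""K-means partitioning of the intrinsic-quality feature space.

:class:`AttentionKMeans` is a from-scratch Lloyd's algorithm with k-means++
seeding and best-of-restarts selection by total within-cluster sum of
squared errors (SSE).  It follows the scikit-learn estimator contract
(``fit`` / ``predict`` / ``get_params``; fitted attributes carry a trailing
underscore) but is an independent implementation — the scikit-learn KMeans
serves only as a cross-check in the test suite.

Determinism and reproducibility choices:

* nearest-centroid ties go to the lowest cluster index;
* an emptied cluster is repaired by moving the point farthest from its
  centroid into it;
* with ``canonicalize=True`` clusters are relabelled by ascending first
  feature coordinate (the span component W) so "cluster k" means the same
  thing across runs and seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = ["AttentionKMeans", "Partition", "kmeans", "sse", "k_selection_report"]

#: the study's working number of quality groups
DEFAULT_K = 4


def _as_matrix(points) -> np.ndarray:
    X = points.to_numpy(dtype=float) if hasattr(points, "to_numpy") else np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise ValueError("points must be a 2-d array-like")
    if not np.all(np.isfinite(X)):
        raise ValueError("points contain non-finite coordinates")
    return X


def _assign(X: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid labels (ties -> lowest index) and squared distances."""
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    return labels, d2[np.arange(len(X)), labels]


def _kmeanspp(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: D^2-weighted sampling of initial centers."""
    n = len(X)
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with a center
            centers[j] = X[rng.integers(n)]
            continue
        centers[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


class AttentionKMeans(BaseEstimator, ClusterMixin):
    """Lloyd's K-means with k-means++ restarts, written for small cohorts.

    Parameters mirror the scikit-learn estimator idiom.  ``n_init`` defaults
    to 50 restarts: the cohorts this package targets have at most a few
    hundred points, and a generous restart budget makes reaching the global
    SSE optimum — and hence run-to-run reproducible tables — the norm.

    Attributes (after ``fit``)
    --------------------------
    cluster_centers_ : (k, n) array
    labels_ : (N,) int array
    inertia_ : float
        Total SSE of the best restart.
    inertia_per_cluster_ : (k,) array
    n_iter_ : int
        Lloyd iterations of the best restart.
    inertia_path_ : list of float
        Total SSE after each Lloyd iteration of the best restart
        (non-increasing by construction).
    """

    def __init__(self, n_clusters: int = DEFAULT_K, n_init: int = 50,
                 max_iter: int = 300, tol: float = 1e-10,
                 random_state: int | None = 0, canonicalize: bool = True):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.canonicalize = canonicalize

    def fit(self, X, y=None) -> "AttentionKMeans":
        X = _as_matrix(X)
        k = self.n_clusters
        if k < 1:
            raise ValueError("n_clusters must be >= 1")
        if k > len(X):
            raise ValueError(f"n_clusters={k} exceeds the {len(X)} points")
        rng = np.random.default_rng(self.random_state)

        best = None
        for _ in range(self.n_init):
            centers, labels, inertia, path = self._lloyd(X, k, rng)
            if best is None or inertia < best[2] - 1e-15:
                best = (centers, labels, inertia, path)
        centers, labels, inertia, path = best

        if self.canonicalize:
            order = np.argsort(centers[:, 0], kind="stable")
            relabel = np.empty(k, dtype=int)
            relabel[order] = np.arange(k)
            centers = centers[order]
            labels = relabel[labels]

        self.cluster_centers_ = centers
        self.labels_ = labels
        self.inertia_ = inertia
        self.inertia_path_ = path
        self.n_iter_ = len(path)
        per = np.zeros(k)
        _, d2 = _assign(X, centers)
        np.add.at(per, labels, d2)
        self.inertia_per_cluster_ = per
        return self

    def _lloyd(self, X: np.ndarray, k: int, rng: np.random.Generator):
        centers = _kmeanspp(X, k, rng)
        labels = np.full(len(X), -1)
        path: list[float] = []
        for _ in range(self.max_iter):
            new_labels, d2 = _assign(X, centers)
            # repair empty clusters with the worst-fitting point
            for j in range(k):
                if not np.any(new_labels == j):
                    far = int(np.argmax(d2))
                    new_labels[far] = j
                    d2[far] = 0.0
            path.append(float(d2.sum()))
            shift = 0.0
            new_centers = centers.copy()
            for j in range(k):
                members = X[new_labels == j]
                if len(members):
                    new_centers[j] = members.mean(axis=0)
                    shift = max(shift, float(np.linalg.norm(new_centers[j] - centers[j])))
            if np.array_equal(new_labels, labels) or shift < self.tol:
                labels, centers = new_labels, new_centers
                break
            labels, centers = new_labels, new_centers
        _, d2 = _assign(X, centers)
        return centers, labels, float(d2.sum()), path

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "cluster_centers_"):
            raise RuntimeError("AttentionKMeans is not fitted")
        labels, _ = _assign(_as_matrix(X), self.cluster_centers_)
        return labels


@dataclass
class Partition:
    """A fitted clustering: assignments, centroids and SSE bookkeeping."""

    K: int
    assignments: np.ndarray
    centroids: np.ndarray
    sse_per_cluster: np.ndarray
    sse_total: float
    n_iter: int
    restarts: int
    seed: int | None
    participant_ids: list[str] | None = None

    @property
    def indicator(self) -> np.ndarray:
        """1-of-K binary indicator matrix, shape (N, K)."""
        eye = np.eye(self.K, dtype=int)
        return eye[self.assignments]

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == k)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.K)


def kmeans(points, k: int = DEFAULT_K, seed: int | None = 0,
           restarts: int = 50, max_iter: int = 300,
           tol: float = 1e-10, canonicalize: bool = True) -> Partition:
    """Cluster a feature matrix (DataFrame or array) into ``k`` groups."""
    model = AttentionKMeans(n_clusters=k, n_init=restarts, max_iter=max_iter,
                            tol=tol, random_state=seed,
                            canonicalize=canonicalize).fit(points)
    ids = list(points.index) if isinstance(points, pd.DataFrame) else None
    return Partition(
        K=k,
        assignments=model.labels_,
        centroids=model.cluster_centers_,
        sse_per_cluster=model.inertia_per_cluster_,
        sse_total=model.inertia_,
        n_iter=model.n_iter_,
        restarts=restarts,
        seed=seed,
        participant_ids=ids,
    )


def sse(points, partition: Partition) -> tuple[np.ndarray, float]:
    """Per-cluster and total sum of squared errors about assigned centroids."""
    X = _as_matrix(points)
    if len(X) != len(partition.assignments):
        raise ValueError("partition does not match the points")
    per = np.zeros(partition.K)
    for j in range(partition.K):
        members = X[partition.assignments == j]
        if len(members):
            per[j] = float(((members - partition.centroids[j]) ** 2).sum())
    return per, float(per.sum())


def k_selection_report(points, k_range=range(1, 7), seed: int | None = 0,
                       restarts: int = 20) -> pd.DataFrame:
    """Best total SSE for each candidate K, with the elbow flagged.

    The elbow is the K with the largest second difference of the *log* SSE
    curve (undefined at the endpoints and wherever SSE reaches 0): relative
    drops make the flattening point visible regardless of the absolute
    scatter scale.  The configured default K=4 is marked for reference;
    SSE is non-increasing in K given enough restarts.
    """
    ks = sorted(k_range)
    rows = []
    for k in ks:
        part = kmeans(points, k=k, seed=seed, restarts=restarts)
        rows.append((k, part.sse_total))
    report = pd.DataFrame(rows, columns=["K", "sse"])
    second_diff = np.full(len(ks), np.nan)
    s = report["sse"].to_numpy()
    with np.errstate(divide="ignore"):
        log_s = np.where(s > 0, np.log(s), -np.inf)
    if len(ks) >= 3:
        sd = log_s[:-2] - 2 * log_s[1:-1] + log_s[2:]
        sd[~np.isfinite(sd)] = np.nan
        second_diff[1:-1] = sd
    report["second_difference"] = second_diff
    report["is_elbow"] = False
    if len(ks) >= 3 and np.any(np.isfinite(second_diff)):
        report.loc[int(np.nanargmax(second_diff)), "is_elbow"] = True
    report["is_default"] = report["K"] == DEFAULT_K
    return report
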