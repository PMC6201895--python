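"""Second-order statistics and inter-cluster metrics for feature clusters.

Per cluster: centroid, size, scalar standard deviation (unbiased, with its
per-dimension version), covariance and correlation matrices, eigenvalue
decomposition into *eigen-features* (the principal axes of the cluster's
scatter), the information-theoretic metric (ITM), and the within-cluster
SSE.  Between clusters: centroid Euclidean distances and the TrLogDet (TLD)
divergence/distance on covariance matrices.

The TLD divergence of SPD matrices A against B is

    div(A, B) = (1/n) [ tr(A B^-1) - ln det(A B^-1) - n ],

a Burg/Stein-type log-det divergence normalised by the dimension; the TLD
distance symmetrises it by averaging.  The ITM of a cluster is its TLD
divergence against the identity ("ideal" unit-scatter cluster).  The ITM is
exposed in two conventions: ``per_dimension`` carries the 1/n factor,
``unnormalized`` is plain ``tr - ln det - n``; reports default to the
unnormalized form (see the methods note for why).

Natural logarithms throughout.  Near-singular covariances are *not*
silently regularized: a singular matrix raises, and a caller who wants a
ridge must add it explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "centroid",
    "euclidean_distances",
    "cluster_dispersion",
    "covariance",
    "correlation",
    "tld_divergence",
    "tld_distance",
    "itm",
    "eigen_features",
    "graham_scan",
    "ClusterStats",
    "PairwiseClusterMetrics",
    "compute_cluster_stats",
]

_SYM_TOL = 1e-12


def _as_points(points) -> np.ndarray:
    X = points.to_numpy(dtype=float) if hasattr(points, "to_numpy") else np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("points contain non-finite values")
    return X


def _check_spd(sigma, name: str = "matrix") -> np.ndarray:
    s = np.asarray(sigma, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(s, s.T, atol=1e-10):
        raise ValueError(f"{name} is not symmetric")
    try:
        np.linalg.cholesky(s)
    except np.linalg.LinAlgError:
        raise ValueError(f"{name} is not positive definite") from None
    return s


def centroid(points) -> np.ndarray:
    """Component-wise mean of the cluster's feature points."""
    X = _as_points(points)
    if len(X) == 0:
        raise ValueError("cluster is empty")
    return X.mean(axis=0)


def euclidean_distances(centroids) -> np.ndarray:
    """Symmetric matrix of pairwise Euclidean distances between centroids."""
    C = _as_points(centroids)
    diff = C[:, None, :] - C[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def cluster_dispersion(points) -> tuple[float, float]:
    """Scalar standard deviation ``sigma`` and its per-dimension version.

    ``sigma**2`` is the mean squared distance to the centroid with the
    unbiased divisor ``N - 1`` (cluster sizes here are small, so the bias
    of the 1/N form would be visible); the per-dimension value is
    ``sigma / sqrt(n)``, comparable across feature-space dimensions.
    """
    X = _as_points(points)
    if len(X) < 2:
        raise ValueError("dispersion needs at least 2 points")
    mu = X.mean(axis=0)
    var = float(((X - mu) ** 2).sum()) / (len(X) - 1)
    sigma = float(np.sqrt(var))
    return sigma, sigma / np.sqrt(X.shape[1])


def covariance(points) -> np.ndarray:
    """Unbiased sample covariance matrix of the cluster's points."""
    X = _as_points(points)
    if len(X) < 2:
        raise ValueError("covariance needs at least 2 points")
    mu = X.mean(axis=0)
    d = X - mu
    return d.T @ d / (len(X) - 1)


def correlation(cov) -> np.ndarray:
    """Pearson normalization ``Cr_ij = S_ij / sqrt(S_ii S_jj)``."""
    s = np.asarray(cov, dtype=float)
    diag = np.diag(s)
    if np.any(diag <= 0):
        raise ValueError("correlation undefined: zero variance in a coordinate")
    scale = np.sqrt(diag)
    return s / np.outer(scale, scale)


def tld_divergence(sigma_k, sigma_i) -> float:
    """Dimension-normalized log-det divergence of ``sigma_k`` from ``sigma_i``.

    Non-negative, zero iff the matrices are equal, and asymmetric in its
    arguments.  Raises if either matrix is not SPD.
    """
    a = _check_spd(sigma_k, "sigma_k")
    b = _check_spd(sigma_i, "sigma_i")
    if a.shape != b.shape:
        raise ValueError("covariance matrices must share a dimension")
    n = a.shape[0]
    m = np.linalg.solve(b, a)  # B^-1 A; trace and det match A B^-1
    sign, logdet = np.linalg.slogdet(m)
    if sign <= 0:
        raise ValueError("log-det undefined for the matrix ratio")
    return float((np.trace(m) - logdet - n) / n)


def tld_distance(sigma_k, sigma_i) -> float:
    """Symmetrized TLD divergence: the average of the two directions."""
    return 0.5 * (tld_divergence(sigma_k, sigma_i) + tld_divergence(sigma_i, sigma_k))


def itm(sigma, convention: str = "unnormalized") -> float:
    """Information-theoretic metric of a covariance against the identity.

    ``per_dimension``: ``(1/n)[tr(S) - ln det(S) - n]`` (identical to the
    TLD divergence from the identity); ``unnormalized`` drops the 1/n.
    Both are >= 0 with equality iff ``S`` is the identity.
    """
    s = _check_spd(sigma, "sigma")
    n = s.shape[0]
    sign, logdet = np.linalg.slogdet(s)
    if sign <= 0:
        raise ValueError("log-det undefined")
    value = float(np.trace(s) - logdet - n)
    if convention == "unnormalized":
        return value
    if convention == "per_dimension":
        return value / n
    raise ValueError(f"unknown ITM convention {convention!r}")


def eigen_features(sigma) -> tuple[np.ndarray, np.ndarray]:
    """Descending eigenvalues and orthonormal eigen-features of a covariance.

    Returns ``(eigenvalues, vectors)`` with vectors in columns, ordered by
    descending eigenvalue.  The sign of each eigen-feature is fixed so its
    largest-magnitude component is positive, making outputs reproducible.
    """
    s = np.asarray(sigma, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(s, s.T, atol=1e-8):
        raise ValueError("matrix is not symmetric")
    vals, vecs = np.linalg.eigh(s)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    for j in range(vecs.shape[1]):
        pivot = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[pivot, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vals, vecs


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def graham_scan(points) -> np.ndarray:
    """Convex hull of a 2-d point set by Graham's scan.

    Vertices are returned counter-clockwise, starting from the lowest-y
    (then lowest-x) point; collinear boundary points are excluded.  Fewer
    than 3 distinct points, or an all-collinear set, degenerate to the
    extreme points of the set (a warning is issued).
    """
    P = _as_points(points)
    if P.shape[1] != 2:
        raise ValueError("graham_scan expects 2-d points")
    uniq = np.unique(P, axis=0)
    if len(uniq) < 3:
        warnings.warn("degenerate hull: fewer than 3 distinct points",
                      stacklevel=2)
        return uniq

    start = min(range(len(uniq)), key=lambda i: (uniq[i, 1], uniq[i, 0]))
    pivot = uniq[start]
    rest = np.delete(uniq, start, axis=0)
    angles = np.arctan2(rest[:, 1] - pivot[1], rest[:, 0] - pivot[0])
    dists = ((rest - pivot) ** 2).sum(axis=1)
    order = np.lexsort((dists, angles))
    rest = rest[order]
    # keep only the farthest of any run of equal angles
    keep = []
    for i in range(len(rest)):
        if i + 1 < len(rest) and np.isclose(angles[order][i], angles[order][i + 1]):
            continue
        keep.append(i)
    rest = rest[keep]

    if len(rest) < 2:
        warnings.warn("degenerate hull: points are collinear", stacklevel=2)
        return np.vstack([pivot, rest]) if len(rest) else pivot[None, :]

    hull = [pivot, rest[0]]
    for p in rest[1:]:
        while len(hull) > 1 and _cross(hull[-2], hull[-1], p) <= 1e-15:
            hull.pop()
        hull.append(p)
    if len(hull) < 3:
        warnings.warn("degenerate hull: points are collinear", stacklevel=2)
    return np.array(hull)


@dataclass
class ClusterStats:
    """Second-order summary of a single cluster."""

    label: int
    size: int
    centroid: np.ndarray
    sigma: float
    sigma_per_dim: float
    covariance: np.ndarray
    correlation: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    itm_unnormalized: float
    itm_per_dimension: float
    sse: float


@dataclass
class PairwiseClusterMetrics:
    """Inter-cluster matrices: Euclidean (centroids) and TLD (covariances)."""

    euclidean: np.ndarray
    tld_divergence: np.ndarray
    tld_distance: np.ndarray


def compute_cluster_stats(points, assignments, K: int | None = None,
                          ) -> tuple[list[ClusterStats], PairwiseClusterMetrics]:
    """All per-cluster statistics and pairwise metrics for a partition.

    ``points`` is the feature matrix (DataFrame or array), ``assignments``
    the integer cluster labels.  Clusters with fewer than 2 points get NaN
    second-order statistics rather than raising, so a pathological
    partition still yields a report.
    """
    X = _as_points(points)
    labels = np.asarray(assignments, dtype=int)
    if len(labels) != len(X):
        raise ValueError("assignments do not match the points")
    K = K if K is not None else int(labels.max()) + 1
    n = X.shape[1]

    stats: list[ClusterStats] = []
    covs: list[np.ndarray | None] = []
    for k in range(K):
        members = X[labels == k]
        mu = centroid(members) if len(members) else np.full(n, np.nan)
        if len(members) >= 2:
            sig, sig_pd = cluster_dispersion(members)
            cov = covariance(members)
            vals, vecs = eigen_features(cov)
            try:
                corr = correlation(cov)
                itm_u = itm(cov, "unnormalized")
                itm_pd = itm(cov, "per_dimension")
            except ValueError:
                corr = np.full((n, n), np.nan)
                itm_u = itm_pd = float("nan")
            covs.append(cov)
        else:
            sig = sig_pd = float("nan")
            cov = np.full((n, n), np.nan)
            corr = np.full((n, n), np.nan)
            vals, vecs = np.full(n, np.nan), np.full((n, n), np.nan)
            itm_u = itm_pd = float("nan")
            covs.append(None)
        cluster_sse = float(((members - mu) ** 2).sum()) if len(members) else 0.0
        stats.append(ClusterStats(
            label=k, size=int((labels == k).sum()), centroid=mu,
            sigma=sig, sigma_per_dim=sig_pd, covariance=cov,
            correlation=corr, eigenvalues=vals, eigenvectors=vecs,
            itm_unnormalized=itm_u, itm_per_dimension=itm_pd,
            sse=cluster_sse,
        ))

    centers = np.vstack([s.centroid for s in stats])
    div = np.zeros((K, K))
    dist = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            if a == b:
                continue
            if covs[a] is None or covs[b] is None:
                div[a, b] = dist[a, b] = float("nan")
                continue
            try:
                div[a, b] = tld_divergence(covs[a], covs[b])
            except ValueError:
                div[a, b] = float("nan")
    for a in range(K):
        for b in range(a + 1, K):
            dist[a, b] = dist[b, a] = 0.5 * (div[a, b] + div[b, a])
    metrics = PairwiseClusterMetrics(
        euclidean=euclidean_distances(centers),
        tld_divergence=div,
        tld_distance=dist,
    )
    return stats, metrics
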