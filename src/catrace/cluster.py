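"""K-means clustering and silhouette scoring.

K-means follows the classic Lloyd iteration with random initial centroids
chosen among the data points: assignment c_i = argmin_k ‖x_i − μ_k‖²
(ties toward the lowest cluster index), update μ_k = mean of C_k, repeated
until assignments stabilize.  The best of ``n_restarts`` seeded restarts
by inertia is kept; an emptied cluster is re-seeded from the point
farthest from its centroid.  Works on 2-D embeddings and on raw
full-dimensional trace matrices alike.

The silhouette of point i is s(i) = (b(i) − a(i)) / max(a(i), b(i)) with
a(i) the mean distance to its own cluster (excluding itself) and b(i) the
smallest mean distance to another cluster; singletons score 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ClusterResult:
    K: int
    assignments: np.ndarray
    centroids: np.ndarray
    inertia: float
    silhouette_points: np.ndarray | None = None
    silhouette_clusters: dict[int, float] | None = None
    silhouette_overall: float | None = None
    composition: pd.DataFrame | None = None
    purity: np.ndarray | None = None
    inertia_history: list[float] = field(default_factory=list)


def _assign(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)  # argmin takes the lowest index on ties


def _lloyd(points: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int, init: str) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    n = points.shape[0]
    if init == "k-means++":
        centroids = _kmeanspp_init(points, k, rng)
    else:
        centroids = points[rng.choice(n, size=k, replace=False)].copy()
    assignments = _assign(points, centroids)
    history: list[float] = []
    for _ in range(max_iter):
        for j in range(k):
            members = points[assignments == j]
            if members.shape[0] == 0:
                # re-seed an empty cluster from the globally farthest point
                d2 = ((points - centroids[_assign(points, centroids)]) ** 2).sum(axis=1)
                centroids[j] = points[int(np.argmax(d2))]
            else:
                centroids[j] = members.mean(axis=0)
        new_assignments = _assign(points, centroids)
        inertia = float(((points - centroids[new_assignments]) ** 2).sum())
        history.append(inertia)
        if np.array_equal(new_assignments, assignments):
            assignments = new_assignments
            break
        assignments = new_assignments
    inertia = float(((points - centroids[assignments]) ** 2).sum())
    return assignments, centroids, inertia, history


def _kmeanspp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = points.shape[0]
    centroids = [points[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(((points[:, None, :] - np.array(centroids)[None]) ** 2).sum(axis=2), axis=1)
        probs = d2 / max(d2.sum(), 1e-300)
        centroids.append(points[rng.choice(n, p=probs)])
    return np.array(centroids, dtype=float)


def kmeans(points: np.ndarray, k: int, seed: int = 0, n_restarts: int = 10,
           max_iter: int = 300, init: str = "random") -> ClusterResult:
    """Seeded Lloyd K-means, best of ``n_restarts`` by inertia."""
    points = np.asarray(points, dtype=float)
    if k < 2:
        raise ValueError("K must be >= 2")
    if points.shape[0] < k:
        raise ValueError(f"K={k} exceeds the number of points ({points.shape[0]})")
    rng = np.random.default_rng(seed)
    best: tuple | None = None
    for _ in range(n_restarts):
        result = _lloyd(points, k, rng, max_iter, init)
        if best is None or result[2] < best[2]:
            best = result
    assignments, centroids, inertia, history = best
    return ClusterResult(K=k, assignments=assignments, centroids=centroids,
                         inertia=inertia, inertia_history=history)


def silhouette(points: np.ndarray, assignments: np.ndarray
               ) -> tuple[np.ndarray, dict[int, float], float]:
    """Per-point, per-cluster, and overall silhouette scores."""
    points = np.asarray(points, dtype=float)
    assignments = np.asarray(assignments)
    clusters = np.unique(assignments)
    if clusters.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n = points.shape[0]
    dists = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2))
    s = np.zeros(n)
    for i in range(n):
        own = assignments[i]
        own_mask = assignments == own
        n_own = own_mask.sum()
        if n_own == 1:
            s[i] = 0.0  # singleton convention
            continue
        a = dists[i, own_mask].sum() / (n_own - 1)  # excludes self (distance 0)
        b = min(dists[i, assignments == other].mean()
                for other in clusters if other != own)
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    per_cluster = {int(c): float(s[assignments == c].mean()) for c in clusters}
    return s, per_cluster, float(s.mean())


def composition_table(assignments: np.ndarray, labels: np.ndarray
                      ) -> tuple[pd.DataFrame, np.ndarray]:
    """Row-normalized cluster × group fraction matrix and per-cluster purity."""
    assignments = np.asarray(assignments)
    labels = np.asarray(labels)
    if assignments.shape[0] != labels.shape[0]:
        raise ValueError("assignments and labels must have equal length")
    table = pd.crosstab(pd.Series(assignments, name="cluster"),
                        pd.Series(labels, name="group"))
    frac = table.div(table.sum(axis=1), axis=0)
    purity = frac.max(axis=1).to_numpy()
    return frac, purity


def cluster_with_scores(points: np.ndarray, labels: np.ndarray, k: int,
                        seed: int = 0, n_restarts: int = 10) -> ClusterResult:
    """K-means plus silhouettes, composition table, and purity in one call."""
    result = kmeans(points, k, seed=seed, n_restarts=n_restarts)
    s, per_cluster, overall = silhouette(points, result.assignments)
    result.silhouette_points = s
    result.silhouette_clusters = per_cluster
    result.silhouette_overall = overall
    result.composition, result.purity = composition_table(result.assignments, labels)
    return result
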