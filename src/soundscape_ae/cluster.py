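"""K-means clustering and internal validity indices.

Lloyd's algorithm with k-means++ seeding partitions feature vectors
(full 5,184-d embeddings or their reduced projections) into k clusters by
minimizing the energy

    E(C) = (1/N) Σ_i ||x_i − c(a_i)||²,

the mean squared Euclidean distance of each sample to its nearest
centroid.  Cluster quality is scored with three standard internal indices:

* Silhouette — per sample, (b−a)/max(a,b) with a the mean intra-cluster
  distance (excluding self) and b the smallest mean distance to another
  cluster; averaged over samples.  Singleton clusters score 0.
* Calinski–Harabasz — Tr(B_k)/Tr(W_k) · (N−k)/(k−1), the between/within
  scatter ratio; larger is better.
* Davies–Bouldin — mean over clusters of the worst (σ_i+σ_j)/d(c_i,c_j)
  with σ the mean distance of a cluster's points to its centroid; smaller
  is better.

All distances are Euclidean; nearest-centroid ties break to the lowest
cluster index.  ``k_sweep`` reproduces the K-vs-metrics table layout used
to pick the number of clusters (K from 3 to 35, plus Mean and STD rows).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

__all__ = [
    "DEFAULT_K_SWEEP",
    "ClusterModel",
    "ValidityReport",
    "kmeans",
    "validity_metrics",
    "k_sweep",
]

DEFAULT_K_SWEEP = (3, 5, 7, 10, 15, 20, 25, 30, 35)


@dataclass(frozen=True)
class ClusterModel:
    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    energy: float
    feature_space: str = "full_embedding"
    seed: int = 0

    def __post_init__(self):
        a = np.asarray(self.assignments)
        if a.min() < 0 or a.max() >= self.k:
            raise ValueError("assignments contain out-of-range cluster indices")
        if len(np.unique(a)) != self.k:
            raise ValueError("model contains empty clusters")


@dataclass(frozen=True)
class ValidityReport:
    silhouette_avg: float
    silhouette_samples: np.ndarray
    calinski_harabasz: float
    davies_bouldin: float


def _pairwise_sq(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, clipped at 0 against rounding."""
    d2 = (
        np.sum(X * X, axis=1)[:, None]
        + np.sum(C * C, axis=1)[None, :]
        - 2.0 * (X @ C.T)
    )
    return np.maximum(d2, 0.0)


def _energy(X: np.ndarray, centroids: np.ndarray, assignments: np.ndarray) -> float:
    diff = X - centroids[assignments]
    return float(np.mean(np.sum(diff * diff, axis=1)))


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = len(X)
    centroids = np.empty((k, X.shape[1]), dtype=np.float64)
    centroids[0] = X[rng.integers(n)]
    d2 = _pairwise_sq(X, centroids[:1]).ravel()
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with chosen centroids
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=d2 / total)
        centroids[j] = X[idx]
        d2 = np.minimum(d2, _pairwise_sq(X, centroids[j : j + 1]).ravel())
    return centroids


def _lloyd(X: np.ndarray, centroids: np.ndarray, max_iter: int, tol: float):
    """Lloyd iterations from given centroids; returns (centroids, assignments, energy).

    The energy is checked to be non-increasing every iteration; empty
    clusters are repaired by reseeding to the farthest point.
    """
    n, k = len(X), len(centroids)
    prev_assign = None
    prev_energy = np.inf
    for _ in range(max_iter):
        d2 = _pairwise_sq(X, centroids)
        assign = np.argmin(d2, axis=1)  # argmin ties break to lowest index
        for j in range(k):  # empty-cluster repair: reseed to the farthest point
            if not np.any(assign == j):
                far = int(np.argmax(d2[np.arange(n), assign]))
                centroids[j] = X[far]
                d2 = _pairwise_sq(X, centroids)
                assign = np.argmin(d2, axis=1)
                assign[far] = j
                prev_energy = np.inf  # repair may transiently raise the energy
        energy = _energy(X, centroids, assign)
        if energy > prev_energy + 1e-7 * max(1.0, prev_energy):
            raise AssertionError("Lloyd energy increased between iterations")
        prev_energy = energy
        if prev_assign is not None and np.array_equal(assign, prev_assign):
            break
        prev_assign = assign
        new_centroids = centroids.copy()
        for j in range(k):
            new_centroids[j] = X[assign == j].mean(axis=0)
        if np.max(np.abs(new_centroids - centroids)) <= tol:
            centroids = new_centroids
            d2 = _pairwise_sq(X, centroids)
            assign = np.argmin(d2, axis=1)
            break
        centroids = new_centroids
    final_energy = _energy(X, centroids, assign)
    return centroids, assign, final_energy


def kmeans(
    features: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-8,
    n_restarts: int = 10,
    feature_space: str = "full_embedding",
) -> ClusterModel:
    """K-means via Lloyd's algorithm with k-means++ seeding and restarts.

    The best-energy solution over ``n_restarts`` seeded initializations is
    returned; deterministic in ``seed``.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    n = len(X)
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"cannot form {k} clusters from {n} samples")

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        init = _kmeanspp_init(X, k, rng)
        centroids, assign, energy = _lloyd(X, init, max_iter, tol)
        if best is None or energy < best[2]:
            best = (centroids, assign, energy)
    centroids, assign, energy = best
    return ClusterModel(
        k=k,
        centroids=centroids,
        assignments=assign,
        energy=energy,
        feature_space=feature_space,
        seed=seed,
    )


def validity_metrics(features: np.ndarray, model: ClusterModel) -> ValidityReport:
    """Silhouette, Calinski–Harabasz and Davies–Bouldin for one clustering."""
    X = np.asarray(features, dtype=np.float64)
    assign = np.asarray(model.assignments)
    k, n = model.k, len(X)
    if k < 2:
        raise ValueError("validity metrics require k >= 2 (silhouette undefined for k = 1)")
    if n < k + 1:
        raise ValueError("need at least k + 1 samples")

    # silhouette: per-sample mean distance to every cluster (exact distances,
    # not the expanded quadratic form, to keep oracle-level precision)
    from scipy.spatial.distance import cdist

    dist = cdist(X, X)
    sizes = np.bincount(assign, minlength=k)
    sums = np.zeros((n, k))
    for j in range(k):
        sums[:, j] = dist[:, assign == j].sum(axis=1)
    sil = np.zeros(n)
    for i in range(n):
        ci = assign[i]
        if sizes[ci] <= 1:
            sil[i] = 0.0  # singleton convention
            continue
        a = sums[i, ci] / (sizes[ci] - 1)
        b = np.inf
        for j in range(k):
            if j != ci:
                b = min(b, sums[i, j] / sizes[j])
        sil[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0

    # Calinski-Harabasz from scatter traces
    overall_mean = X.mean(axis=0)
    centroids = model.centroids
    means = np.stack([X[assign == j].mean(axis=0) for j in range(k)])
    tr_b = float(np.sum(sizes * np.sum((means - overall_mean) ** 2, axis=1)))
    tr_w = float(np.sum((X - means[assign]) ** 2))
    ch = (tr_b / tr_w) * (n - k) / (k - 1) if tr_w > 0 else float("inf")

    # Davies-Bouldin with mean point-to-centroid distances
    sigma = np.array(
        [np.mean(np.linalg.norm(X[assign == j] - means[j], axis=1)) for j in range(k)]
    )
    cent_dist = cdist(means, means)
    ratios = np.full((k, k), -np.inf)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            ratios[i, j] = (sigma[i] + sigma[j]) / cent_dist[i, j] if cent_dist[i, j] > 0 else float("inf")
    db = float(np.mean(np.max(ratios, axis=1)))

    return ValidityReport(
        silhouette_avg=float(np.mean(sil)),
        silhouette_samples=sil,
        calinski_harabasz=ch,
        davies_bouldin=db,
    )


def k_sweep(
    features: np.ndarray,
    k_values: Sequence[int] = DEFAULT_K_SWEEP,
    seed: int = 0,
    feature_space: str = "full_embedding",
):
    """Sweep K and tabulate the three validity indices.

    Returns ``(table, best)`` where the table has one row per k plus Mean
    and STD rows, and ``best`` maps each metric to the k at which it is
    best (max for slt/ch, min for db).
    """
    import pandas as pd

    X = np.asarray(features, dtype=np.float64)
    k_values = list(k_values)
    if max(k_values) > len(X) - 1:
        raise ValueError(
            f"max k = {max(k_values)} exceeds n - 1 = {len(X) - 1}; reduce the sweep range"
        )
    rows = []
    for k in k_values:
        model = kmeans(X, k, seed=seed, feature_space=feature_space)
        report = validity_metrics(X, model)
        rows.append(
            {
                "k": k,
                "space": feature_space,
                "slt": report.silhouette_avg,
                "db": report.davies_bouldin,
                "ch": report.calinski_harabasz,
            }
        )
    table = pd.DataFrame(rows)
    best = {
        "slt": int(table.loc[table["slt"].idxmax(), "k"]),
        "db": int(table.loc[table["db"].idxmin(), "k"]),
        "ch": int(table.loc[table["ch"].idxmax(), "k"]),
    }
    summary = pd.DataFrame(
        [
            {"k": "Mean", "space": feature_space, **table[["slt", "db", "ch"]].mean().to_dict()},
            {"k": "STD", "space": feature_space, **table[["slt", "db", "ch"]].std(ddof=0).to_dict()},
        ]
    )
    table = pd.concat([table, summary], ignore_index=True)
    return table, best
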