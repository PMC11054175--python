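"""Dimensionality reduction of autoencoder embeddings.

The 5,184-d latent features are reduced to 60 components for clustering
and classification and to 2 components for visualization, with PCA, t-SNE
or UMAP.  Embeddings are min-max normalized per feature beforehand by
default (the features are non-negative post-ReLU activations, so min-max
respects their natural range).  PCA also answers the "how many components
keep 90% of the variance" question.  PCA and UMAP support mapping reduced
points back to the embedding space, which is what lets cluster centroids
found in a reduced space be decoded into prototype spectrograms; t-SNE has
no inverse and raises.

t-SNE beyond 3 output dimensions routes to the exact O(n²) algorithm
(tree-accelerated implementations cap at 3); for large corpora subsample
before calling it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ProjectionModel",
    "FeatureNormalizer",
    "normalize_features",
    "fit_project",
    "select_pca_components",
    "inverse_project",
    "InverseNotSupportedError",
]

PROJECTION_METHODS = ("pca", "tsne", "umap")


class InverseNotSupportedError(NotImplementedError):
    """The projection method has no inverse mapping."""


@dataclass
class FeatureNormalizer:
    """Per-feature min-max scaling fitted on the data it will transform."""

    mins: np.ndarray
    ranges: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureNormalizer":
        mins = X.min(axis=0)
        ranges = X.max(axis=0) - mins
        ranges = np.where(ranges > 0, ranges, 1.0)
        return cls(mins=mins, ranges=ranges)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mins) / self.ranges

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        return X * self.ranges + self.mins


def normalize_features(X: np.ndarray) -> np.ndarray:
    return FeatureNormalizer.fit(X).transform(X)


@dataclass
class ProjectionModel:
    """A fitted reducer plus the normalizer applied before it.

    For UMAP the training pairs (reduced coordinates, normalized inputs)
    are retained: the inverse mapping interpolates them by nearest
    neighbors, which stays tractable at any output dimensionality.
    """

    method: str
    n_components: int
    fitted_state: object
    seed: int
    normalizer: Optional[FeatureNormalizer] = None
    explained_variance_ratio: Optional[np.ndarray] = None
    train_coords: Optional[np.ndarray] = None
    train_inputs: Optional[np.ndarray] = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.method == "tsne":
            raise InverseNotSupportedError("t-SNE cannot transform out-of-sample points")
        Xn = self.normalizer.transform(X) if self.normalizer is not None else X
        return np.asarray(self.fitted_state.transform(Xn))


def fit_project(
    embeddings: np.ndarray,
    method: str = "umap",
    n_components: int = 60,
    seed: int = 0,
    normalize: bool = True,
    perplexity: float = 30.0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
):
    """Fit a reducer → (ProjectionModel, n×n_components coordinates)."""
    X = np.asarray(embeddings, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("embeddings must be a 2-D matrix")
    n = X.shape[0]
    if n < n_components + 1:
        raise ValueError(f"need at least n_components + 1 = {n_components + 1} samples, got {n}")
    if method not in PROJECTION_METHODS:
        raise ValueError(f"method {method!r} not in {PROJECTION_METHODS}")

    normalizer = FeatureNormalizer.fit(X) if normalize else None
    Xn = normalizer.transform(X) if normalizer is not None else X

    evr = None
    if method == "pca":
        from sklearn.decomposition import PCA

        reducer = PCA(n_components=n_components, svd_solver="full", random_state=seed)
        coords = reducer.fit_transform(Xn)
        evr = reducer.explained_variance_ratio_.copy()
    elif method == "tsne":
        from sklearn.manifold import TSNE

        algo = "exact" if n_components > 3 else "barnes_hut"
        reducer = TSNE(
            n_components=n_components,
            method=algo,
            perplexity=min(perplexity, max(2.0, (n - 1) / 3.0)),
            init="random",
            random_state=seed,
        )
        coords = reducer.fit_transform(Xn)
    else:
        import umap

        reducer = umap.UMAP(
            n_components=n_components,
            n_neighbors=min(n_neighbors, n - 1),
            min_dist=min_dist,
            random_state=seed,
        )
        coords = reducer.fit_transform(Xn)

    coords = np.asarray(coords, dtype=np.float64)
    model = ProjectionModel(
        method=method,
        n_components=n_components,
        fitted_state=reducer,
        seed=seed,
        normalizer=normalizer,
        explained_variance_ratio=evr,
        train_coords=coords.copy() if method == "umap" else None,
        train_inputs=np.asarray(Xn, dtype=np.float64) if method == "umap" else None,
    )
    return model, coords


def select_pca_components(
    embeddings: np.ndarray, variance_target: float = 0.9, normalize: bool = True
) -> int:
    """Smallest number of principal components whose cumulative explained
    variance reaches ``variance_target`` (default: the 90% rule)."""
    if not 0.0 < variance_target <= 1.0:
        raise ValueError(f"variance_target {variance_target} not in (0, 1]")
    from sklearn.decomposition import PCA

    X = np.asarray(embeddings, dtype=np.float64)
    Xn = normalize_features(X) if normalize else X
    pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1]), svd_solver="full")
    pca.fit(Xn)
    cum = np.cumsum(pca.explained_variance_ratio_)
    hits = np.flatnonzero(cum >= variance_target - 1e-12)
    return int(hits[0]) + 1 if hits.size else len(cum)


def _knn_inverse(model: ProjectionModel, pts: np.ndarray, k: int = 5) -> np.ndarray:
    """Barycentric inverse for UMAP: inverse-distance-weighted average of the
    nearest training inputs in the reduced space.  A point coinciding with a
    training coordinate maps back to that training input exactly."""
    coords, inputs = model.train_coords, model.train_inputs
    k = min(k, len(coords))
    d2 = (
        np.sum(pts * pts, axis=1)[:, None]
        + np.sum(coords * coords, axis=1)[None, :]
        - 2.0 * pts @ coords.T
    )
    d2 = np.maximum(d2, 0.0)
    nn = np.argsort(d2, axis=1)[:, :k]
    out = np.empty((len(pts), inputs.shape[1]))
    for i in range(len(pts)):
        dd = np.sqrt(d2[i, nn[i]])
        if dd[0] < 1e-12:
            out[i] = inputs[nn[i][0]]
            continue
        w = 1.0 / dd
        out[i] = (w[:, None] * inputs[nn[i]]).sum(axis=0) / w.sum()
    return out


def inverse_project(model: ProjectionModel, points: np.ndarray) -> np.ndarray:
    """Map reduced-space points back to the embedding space.

    PCA inverts exactly on its retained subspace.  UMAP uses a k-nearest-
    neighbor barycentric interpolation of its training pairs (the library's
    own simplicial inverse is limited to very low output dimensionality).
    t-SNE raises :class:`InverseNotSupportedError`.
    """
    if model.method == "tsne":
        raise InverseNotSupportedError("t-SNE defines no inverse mapping")
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if pts.shape[1] != model.n_components:
        raise ValueError(f"points have {pts.shape[1]} columns, model expects {model.n_components}")
    if model.method == "umap":
        back = _knn_inverse(model, pts)
    else:
        back = np.asarray(model.fitted_state.inverse_transform(pts), dtype=np.float64)
    if model.normalizer is not None:
        back = model.normalizer.inverse_transform(back)
    return back
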