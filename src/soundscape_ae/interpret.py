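"""Cluster interpretation: prototype spectrograms and diel patterns.

A cluster found in feature space is summarized two ways:

* a *prototype spectrogram* — the decoder's rendering of the cluster's
  representative feature vector, either the element-wise mean of the
  member embeddings (``mean_embedding``) or the reduced-space centroid
  mapped back through the projection's inverse and then decoded
  (``inverse_projection``; PCA/UMAP only).  When clustering was done in
  the full embedding space the two pathways coincide, since the centroid
  *is* the mean embedding.
* a *diel histogram* — counts of member segments per hour of day (0-23),
  revealing nocturnal/diurnal activity.  Hours are local wall-clock
  integers; no sunrise normalization is applied (appropriate for
  equatorial study sites where day length barely varies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .cae import ConvAutoencoder
from .cluster import ClusterModel
from .project import InverseNotSupportedError, ProjectionModel, inverse_project
from .spectro import N_BINS

__all__ = ["PrototypeSpectrogram", "DielHistogram", "prototype_spectrogram", "diel_histograms"]

logger = logging.getLogger(__name__)

PATHWAYS = ("mean_embedding", "inverse_projection", "auto")


@dataclass(frozen=True)
class PrototypeSpectrogram:
    cluster_index: int
    values: np.ndarray
    pathway: str
    feature_space: str
    k: int

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.shape != (N_BINS, N_BINS):
            raise ValueError(f"prototype shape {v.shape} != ({N_BINS}, {N_BINS})")

    def band_argmax_bin(self) -> int:
        """Frequency bin with the highest time-averaged energy — the
        prototype's dominant spectral band."""
        return int(np.argmax(np.asarray(self.values).mean(axis=1)))


@dataclass(frozen=True)
class DielHistogram:
    cluster_index: int
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (24,) or np.any(c < 0):
            raise ValueError("counts must be 24 non-negative integers")

    def mass_in_hours(self, hours: Sequence[int]) -> float:
        """Fraction of the cluster's segments falling in the given hours."""
        total = int(np.sum(self.counts))
        if total == 0:
            return 0.0
        return float(np.sum(self.counts[list(hours)])) / total


def prototype_spectrogram(
    model: ClusterModel,
    cae_model: ConvAutoencoder,
    cluster_index: int,
    projection: Optional[ProjectionModel] = None,
    member_embeddings: Optional[np.ndarray] = None,
    pathway: str = "auto",
) -> PrototypeSpectrogram:
    """Decode a cluster's representative feature vector into a spectrogram.

    ``auto`` resolves to ``inverse_projection`` when the clustering ran in
    an invertible reduced space (PCA/UMAP projection supplied), else to
    ``mean_embedding`` (requires the cluster members' 5,184-d embeddings).
    """
    if pathway not in PATHWAYS:
        raise ValueError(f"pathway {pathway!r} not in {PATHWAYS}")
    if not 0 <= cluster_index < model.k:
        raise ValueError(f"cluster_index {cluster_index} out of range for k={model.k}")

    if pathway == "auto":
        invertible = projection is not None and projection.method in ("pca", "umap")
        pathway = "inverse_projection" if invertible else "mean_embedding"

    if pathway == "inverse_projection":
        if projection is None:
            raise ValueError("inverse_projection pathway requires a fitted projection model")
        if projection.method == "tsne":
            raise InverseNotSupportedError("t-SNE projections cannot be inverted")
        embedding = inverse_project(projection, model.centroids[cluster_index][None])[0]
    else:
        if member_embeddings is None:
            raise ValueError("mean_embedding pathway requires the cluster members' embeddings")
        members = np.asarray(member_embeddings)[np.asarray(model.assignments) == cluster_index]
        if len(members) == 0:
            raise ValueError(f"cluster {cluster_index} has no members")
        embedding = members.mean(axis=0)

    values = np.clip(cae_model.decode(embedding), 0.0, 1.0)
    return PrototypeSpectrogram(
        cluster_index=cluster_index,
        values=values,
        pathway=pathway,
        feature_space=model.feature_space,
        k=model.k,
    )


def diel_histograms(
    assignments: Sequence[int], hours: Sequence, k: int
) -> List[DielHistogram]:
    """Per-cluster hour-of-day histograms.

    ``hours`` holds each segment's hour (0-23) aligned with ``assignments``;
    missing values raise with the offending positions listed.  The
    histograms conserve counts: summed over clusters they reproduce the
    global hourly distribution.
    """
    assign = np.asarray(assignments)
    hrs = np.asarray(hours, dtype=object)
    missing = [i for i, h in enumerate(hrs) if h is None or (isinstance(h, float) and np.isnan(h))]
    if missing:
        raise ValueError(f"segments without an hour-of-day at positions {missing}")
    hrs = hrs.astype(int)
    if hrs.min() < 0 or hrs.max() > 23:
        raise ValueError("hours must lie in [0, 23]")
    if len(assign) != len(hrs):
        raise ValueError("assignments and hours must align")

    out = []
    for j in range(k):
        counts = np.bincount(hrs[assign == j], minlength=24)[:24]
        if counts.sum() == 0:
            logger.warning("cluster %d is empty; all-zero diel histogram", j)
        out.append(DielHistogram(cluster_index=j, counts=counts))
    return out
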