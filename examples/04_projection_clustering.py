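"""Reduce feature vectors, cluster them, and score cluster validity.

Three synthetic "acoustic classes" in feature space are projected to 2-D
with UMAP and clustered with K-means over a sweep of K.  The validity
indices (Silhouette, Davies–Bouldin, Calinski–Harabasz) all prefer the
planted K = 3.
"""

import numpy as np

from soundscape_ae import fit_project, k_sweep, kmeans, select_pca_components, validity_metrics

rng = np.random.default_rng(0)
centers = rng.standard_normal((3, 64)) * 12.0
features = np.concatenate([c + rng.standard_normal((50, 64)) for c in centers])

k = select_pca_components(features, variance_target=0.9, normalize=False)
print(f"PCA components needed for 90% variance: {k}")

model_2d, coords = fit_project(features, method="umap", n_components=2, seed=0, normalize=False)

table, best = k_sweep(coords, k_values=[2, 3, 4, 5, 7], seed=0, feature_space="umap")
print(table.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print(f"best k per metric: {best}")  # silhouette/CH maximal, DB minimal at k=3

cm = kmeans(coords, 3, seed=0, feature_space="umap")
report = validity_metrics(coords, cm)
print(f"k=3: energy {cm.energy:.3f}, silhouette {report.silhouette_avg:.3f}")
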