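"""Projection: PCA variance rules, UMAP separation and inverses, t-SNE routing."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from soundscape_ae import (
    fit_project,
    inverse_project,
    kmeans,
    normalize_features,
    select_pca_components,
)
from soundscape_ae.project import InverseNotSupportedError


def _blobs(n=200, d=10, centers=2, spread=20.0, seed=0):
    rng = np.random.default_rng(seed)
    means = rng.standard_normal((centers, d)) * spread
    labels = np.repeat(np.arange(centers), n // centers)
    X = means[labels] + rng.standard_normal((len(labels), d))
    return X, labels


def _data_with_exact_variances(variances, n=400, seed=0):
    """Samples whose empirical covariance eigenvalues equal ``variances`` exactly."""
    rng = np.random.default_rng(seed)
    d = len(variances)
    A = rng.standard_normal((n, d))
    A -= A.mean(axis=0)
    U, _, _ = np.linalg.svd(A, full_matrices=False)
    return U * np.sqrt(np.asarray(variances) * (n - 1))


class TestPCA:
    def test_exact_subspace_captures_all_variance(self):
        rng = np.random.default_rng(0)
        basis = rng.standard_normal((3, 50))
        X = rng.standard_normal((100, 3)) @ basis + 5.0
        model, coords = fit_project(X, "pca", 3, seed=0, normalize=False)
        assert coords.shape == (100, 3)
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)

    def test_component_count_from_cumulative_variance(self):
        """Variance fractions (0.5, 0.4, 0.1): smallest k with cumulative >= 0.9 is 2."""
        X = _data_with_exact_variances([0.5, 0.4, 0.1])
        assert select_pca_components(X, 0.9, normalize=False) == 2

    def test_isotropic_gaussian_needs_nine_of_ten(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((2_000, 10))
        assert select_pca_components(X, 0.9, normalize=False) == 9

    def test_rank_one_needs_single_component(self):
        rng = np.random.default_rng(2)
        X = np.outer(rng.standard_normal(100), rng.standard_normal(20))
        assert select_pca_components(X, 0.99, normalize=False) == 1

    def test_full_variance_on_full_rank_needs_all(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 6))
        assert select_pca_components(X, 1.0, normalize=False) == 6

    def test_lossless_round_trip_on_captured_subspace(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((50, 4)) @ rng.standard_normal((4, 30))
        model, coords = fit_project(X, "pca", 4, seed=0, normalize=False)
        back = inverse_project(model, coords)
        assert np.max(np.abs(back - X)) < 1e-6

    def test_inverse_of_projected_mean_is_data_mean(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((80, 12))
        model, coords = fit_project(X, "pca", 5, seed=0, normalize=False)
        back = inverse_project(model, coords.mean(axis=0)[None])[0]
        np.testing.assert_allclose(back, X.mean(axis=0), atol=1e-8)

    def test_distance_preservation_within_discarded_variance(self):
        """Mean squared pairwise distance shrinks by at most the discarded variance share."""
        rng = np.random.default_rng(6)
        X = rng.standard_normal((120, 15)) * np.linspace(3, 0.1, 15)
        model, coords = fit_project(X, "pca", 6, seed=0, normalize=False)
        def msd(A):
            d2 = np.sum((A[:, None] - A[None]) ** 2, axis=-1)
            return d2.mean()
        retained = model.explained_variance_ratio.sum()
        assert msd(coords) >= retained * msd(X - X.mean(axis=0)) * 0.999


class TestUMAP:
    def test_separated_blobs_recovered_in_2d(self):
        X, labels = _blobs(seed=7)
        _, coords = fit_project(X, "umap", 2, seed=0, normalize=False)
        model = kmeans(coords, 2, seed=0)
        assert adjusted_rand_score(labels, model.assignments) >= 0.99

    def test_inverse_maps_training_points_home(self):
        """>=80% of projected training points invert to their own neighborhood."""
        X, _ = _blobs(n=100, seed=8)
        model, coords = fit_project(X, "umap", 2, seed=0, normalize=False)
        back = inverse_project(model, coords)
        hits = 0
        for i in range(len(X)):
            d = np.linalg.norm(X - back[i], axis=1)
            hits += int(np.argmin(d) == i)
        assert hits / len(X) >= 0.8

    def test_deterministic_under_seed(self):
        X, _ = _blobs(n=80, seed=9)
        _, c1 = fit_project(X, "umap", 2, seed=3, normalize=False)
        _, c2 = fit_project(X, "umap", 2, seed=3, normalize=False)
        np.testing.assert_array_equal(c1, c2)


class TestTSNE:
    def test_high_dimensional_output_routes_to_exact_method(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((60, 20))
        model, coords = fit_project(X, "tsne", 10, seed=0, normalize=False)
        assert coords.shape == (60, 10)
        assert model.fitted_state.method == "exact"

    def test_inverse_raises_capability_error(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((50, 10))
        model, coords = fit_project(X, "tsne", 2, seed=0, normalize=False)
        with pytest.raises(InverseNotSupportedError):
            inverse_project(model, coords[:3])


class TestContracts:
    def test_row_count_preserved_and_column_count_exact(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((70, 40))
        for method in ("pca", "umap"):
            _, coords = fit_project(X, method, 5, seed=0)
            assert coords.shape == (70, 5)

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError, match="at least"):
            fit_project(np.zeros((10, 20)), "pca", 10, seed=0)

    def test_normalization_maps_features_to_unit_range(self):
        rng = np.random.default_rng(13)
        X = rng.random((30, 5)) * 100 + 7
        Xn = normalize_features(X)
        np.testing.assert_allclose(Xn.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Xn.max(axis=0), 1.0, atol=1e-12)
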