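"""Subsampling, normalization, PCA, feature weights, and clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repfp.clonotype_io import FeatureSpace, VJCountTable
from repfp.fingerprint_core import (
    ClusterSpec,
    Embedding,
    FeatureMatrix,
    NormalizationSpec,
    PCAModel,
    SubsampleSpec,
    build_replicate_matrix,
    feature_weights,
    fit_pca,
    kmeans_cluster,
    project,
    subsample_replicates,
    zscore_normalize,
)


def _matrix(values, names=None):
    values = np.asarray(values, dtype=np.float64)
    n, k = values.shape
    return FeatureMatrix(
        donors=tuple(f"d{i}" for i in range(n)),
        replicate_ids=tuple(0 for _ in range(n)),
        feature_names=tuple(names or (f"f{j}" for j in range(k))),
        values=values,
    )


class TestSubsampling:
    def test_single_support_point(self):
        rows = subsample_replicates([7, 0], SubsampleSpec(depth=10, n_replicates=4))
        assert (rows == [10, 0]).all()

    def test_rows_sum_exactly_to_depth(self):
        spec = SubsampleSpec(depth=100_000, n_replicates=10, seed=3)
        rows = subsample_replicates([5, 200, 17, 3000], spec)
        assert rows.shape == (10, 4)
        assert (rows.sum(axis=1) == 100_000).all()

    def test_mean_fraction_within_binomial_bound(self):
        spec = SubsampleSpec(depth=100_000, n_replicates=10, seed=0)
        rows = subsample_replicates([900, 100], spec)
        mean_fraction = rows[:, 0].mean() / spec.depth
        bound = 3 * np.sqrt(0.9 * 0.1 / spec.depth)
        assert abs(mean_fraction - 0.9) < bound

    def test_all_zero_counts_name_the_donor(self):
        with pytest.raises(ValueError, match="HIP7"):
            subsample_replicates([0, 0], SubsampleSpec(), donor_id="HIP7")

    def test_donor_stream_unaffected_by_other_donors(self):
        space = FeatureSpace(("A_B", "C_D"))
        spec = SubsampleSpec(depth=1000, n_replicates=3, seed=5)
        two = VJCountTable(("d1", "d2"), space, np.array([[5, 5], [1, 9]]))
        three = VJCountTable(
            ("d0", "d1", "d2"), space, np.array([[3, 3], [5, 5], [1, 9]])
        )
        m2, m3 = build_replicate_matrix(two, spec), build_replicate_matrix(three, spec)
        assert (m2.values == m3.values[3:]).all()

    def test_deterministic_given_seed(self):
        spec = SubsampleSpec(depth=500, n_replicates=2, seed=9)
        a = subsample_replicates([3, 4, 5], spec, "x")
        b = subsample_replicates([3, 4, 5], spec, "x")
        assert (a == b).all()


class TestZscoreNormalize:
    def test_worked_example(self):
        out = zscore_normalize(_matrix([[1], [10], [100]]))
        # logs [0,1,2] -> Z = [-sqrt(3/2), 0, sqrt(3/2)] -> 10**Z
        assert out.values[:, 0] == pytest.approx([0.0596, 1.0, 16.7782], abs=1e-3)

    def test_zero_variance_column_maps_to_one(self):
        out = zscore_normalize(_matrix([[5], [5], [5]]))
        assert out.values[:, 0] == pytest.approx([1.0, 1.0, 1.0])

    def test_pseudocount_replaces_zeros(self):
        out = zscore_normalize(_matrix([[0], [0], [1]]))
        # logs are [-2, -2, 0]: the two zero rows share one value below 1
        assert out.values[0, 0] == pytest.approx(out.values[1, 0])
        assert out.values[0, 0] < 1 < out.values[2, 0]
        logs = np.log10(out.values[:, 0])
        assert logs.mean() == pytest.approx(0.0, abs=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            zscore_normalize(_matrix([[1, 2]]))

    @given(
        st.integers(2, 8), st.integers(1, 6),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=40, deadline=None)
    def test_normalized_columns_have_zero_mean_unit_sd_logs(self, n, k, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 50, size=(n, k))
        out = zscore_normalize(_matrix(counts))
        assert (out.values > 0).all()
        logs = np.log10(out.values)
        for j in range(k):
            if np.ptp(np.log10(np.where(counts[:, j] == 0, 0.01, counts[:, j]))) > 0:
                assert logs[:, j].mean() == pytest.approx(0.0, abs=1e-9)
                assert logs[:, j].std() == pytest.approx(1.0, abs=1e-9)
            else:
                assert (out.values[:, j] == 1.0).all()


class TestPCA:
    def test_collinear_rows_put_all_variance_on_pc1(self):
        base = np.array([1.0, -2.0, 0.5])
        values = np.outer([0.0, 1.0, 2.0, 3.0], base) + 5.0
        model = fit_pca(_matrix(values), n_components=2)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(8, 5))
        model = fit_pca(_matrix(values), n_components=4)
        cov = np.cov(values, rowvar=False)
        eigenvalues = np.sort(np.linalg.eigvalsh(cov))[::-1]
        expected = eigenvalues / eigenvalues.sum()
        assert model.explained_variance_ratio == pytest.approx(expected[:4], abs=1e-8)

    def test_identical_rows_degenerate_with_warning(self):
        values = np.tile([1.0, 2.0, 3.0], (4, 1))
        with pytest.warns(UserWarning, match="zero total variance"):
            model = fit_pca(_matrix(values), n_components=2)
        assert (model.explained_variance_ratio == 0).all()

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(_matrix(np.eye(3)), n_components=3)  # rows - 1 == 2

    def test_loadings_orthonormal_and_ratios_valid(self):
        rng = np.random.default_rng(2)
        model = fit_pca(_matrix(rng.normal(size=(9, 6))), n_components=5)
        gram = model.loadings @ model.loadings.T
        assert gram == pytest.approx(np.eye(5), abs=1e-8)
        ratios = model.explained_variance_ratio
        assert (np.diff(ratios) <= 1e-12).all()
        assert ratios.sum() <= 1 + 1e-9

    def test_model_json_round_trip(self, tmp_path):
        model = fit_pca(_matrix(np.random.default_rng(3).normal(size=(6, 4))), 2)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = PCAModel.from_json(path)
        assert loaded.feature_names == model.feature_names
        assert loaded.loadings == pytest.approx(model.loadings)
        assert loaded.mean == pytest.approx(model.mean)


class TestProject:
    def _fitted(self):
        rng = np.random.default_rng(4)
        matrix = _matrix(rng.normal(size=(10, 4)))
        return matrix, fit_pca(matrix, n_components=2)

    def test_training_scores_reproduce_variance_ratios(self):
        matrix, model = self._fitted()
        scores = project(model, matrix).coordinates
        score_var = scores.var(axis=0)
        total = ((matrix.values - matrix.values.mean(axis=0)) ** 2).sum() / len(
            matrix.values
        )
        assert score_var / total == pytest.approx(
            model.explained_variance_ratio, abs=1e-9
        )

    def test_translation_invariance(self):
        matrix, model = self._fitted()
        shifted = _matrix(matrix.values + 7.5)
        # centering removes any constant offset only if the model re-centers
        # on its stored means; equal *relative* geometry means equal
        # pairwise differences of coordinates
        a = project(model, matrix).coordinates
        b = project(model, shifted).coordinates
        assert (a - a[0]) == pytest.approx(b - b[0], abs=1e-9)

    def test_row_at_column_means_maps_to_origin(self):
        matrix, model = self._fitted()
        row = _matrix(model.mean[None, :])
        assert project(model, row).coordinates == pytest.approx(0.0, abs=1e-9)

    def test_feature_mismatch_lists_offenders(self):
        matrix, model = self._fitted()
        renamed = _matrix(matrix.values, names=["x0", "f1", "f2", "f3"])
        with pytest.raises(ValueError, match="x0"):
            project(model, renamed)


class TestFeatureWeights:
    def test_only_varying_feature_tops_pc1(self):
        rng = np.random.default_rng(5)
        values = np.ones((12, 5))
        values[:, 3] = rng.normal(size=12)
        model = fit_pca(_matrix(values), n_components=2)
        weights = feature_weights(model, components=(0,))
        assert weights["PC1"].abs().idxmax() == "f3"
        assert weights.loc["f3", "PC1_rank"] == 1

    def test_unit_norm_and_positive_top_entry(self):
        rng = np.random.default_rng(6)
        model = fit_pca(_matrix(rng.normal(size=(10, 6))), n_components=3)
        weights = feature_weights(model, components=(0, 1, 2))
        for c in ("PC1", "PC2", "PC3"):
            w = weights[c].to_numpy()
            assert np.linalg.norm(w) == pytest.approx(1.0, abs=1e-8)
            assert w[np.argmax(np.abs(w))] >= 0

    def test_invalid_component_rejected(self):
        model = fit_pca(_matrix(np.random.default_rng(7).normal(size=(5, 3))), 2)
        with pytest.raises(ValueError):
            feature_weights(model, components=(5,))


class TestKmeans:
    @staticmethod
    def _embedding(points):
        points = np.asarray(points, dtype=np.float64)
        return Embedding(
            donors=tuple(f"d{i}" for i in range(len(points))),
            replicate_ids=tuple(0 for _ in points),
            coordinates=points,
        )

    def test_perfectly_separated_triples(self):
        emb = self._embedding([(0, 0), (0.1, 0), (0, 0.1), (10, 10), (10.1, 10), (10, 10.1)])
        labels = kmeans_cluster(emb, ClusterSpec(k=2, seed=0)).labels
        assert set(labels[:3]) != set(labels[3:])
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1

    def test_k_one_gives_single_cluster(self):
        emb = self._embedding([(0, 0), (1, 1), (2, 2)])
        assert (kmeans_cluster(emb, ClusterSpec(k=1)).labels == 0).all()

    def test_fewer_rows_than_k_rejected(self):
        emb = self._embedding([(0, 0)])
        with pytest.raises(ValueError):
            kmeans_cluster(emb, ClusterSpec(k=2))

    def test_labels_deterministic_and_centroid_ordered(self):
        rng = np.random.default_rng(8)
        emb = self._embedding(rng.normal(size=(20, 2)))
        a = kmeans_cluster(emb, ClusterSpec(k=3, seed=4))
        b = kmeans_cluster(emb, ClusterSpec(k=3, seed=4))
        assert (a.labels == b.labels).all()
        order = np.lexsort(a.centroids.T[::-1])
        assert (order == np.arange(3)).all()
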