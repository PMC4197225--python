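"""Tests of the pairwise distance matrices and the dispersion distance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from cohortdiversity import (
    CategoricalMatrix,
    DistanceMatrix,
    cosine_distance_matrix,
    dispersion_distances,
    filter_expression,
    gower_center,
    hamming_distance_matrix,
    pearson_distance_matrix,
    summarize_diversity,
)

from conftest import make_expression


def euclidean_dm(points):
    points = np.asarray(points, dtype=float)
    d = squareform(pdist(points))
    return DistanceMatrix(d, [f"p{i}" for i in range(len(points))])


def centroid_distances(points):
    points = np.asarray(points, dtype=float)
    return np.linalg.norm(points - points.mean(axis=0), axis=1)


class TestPearsonDistance:
    def test_identical_columns_have_zero_distance(self):
        X = make_expression(np.tile([[1.0], [2.0], [5.0]], (1, 3)))
        D = pearson_distance_matrix(X)
        np.testing.assert_allclose(D.values, 0.0, atol=1e-12)

    def test_anticorrelated_columns_have_distance_one(self):
        X = make_expression([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]])
        assert pearson_distance_matrix(X).values[0, 1] == pytest.approx(1.0)

    def test_matches_textbook_correlation_formula(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0])
        # independent oracle: explicit sum formula
        n = len(x)
        rho = (n * (x * y).sum() - x.sum() * y.sum()) / np.sqrt(
            (n * (x**2).sum() - x.sum() ** 2) * (n * (y**2).sum() - y.sum() ** 2)
        )
        D = pearson_distance_matrix(make_expression(np.column_stack([x, y])))
        assert D.values[0, 1] == pytest.approx((1 - rho) / 2, abs=1e-12)

    def test_one_minus_rho_scale_doubles_the_default(self):
        X = make_expression(np.random.default_rng(0).normal(size=(10, 4)))
        half = pearson_distance_matrix(X).values
        full = pearson_distance_matrix(X, scale="one-minus-rho").values
        np.testing.assert_allclose(full, 2 * half, atol=1e-12)

    def test_constant_column_error_names_the_sample(self):
        X = make_expression([[1.0, 2.0], [1.0, 3.0]], samples=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            pearson_distance_matrix(X)

    def test_gene_subset_restricts_the_correlation(self):
        rng = np.random.default_rng(1)
        X = make_expression(rng.normal(size=(20, 5)))
        sub = pearson_distance_matrix(X, genes=X.gene_ids[:10])
        direct = pearson_distance_matrix(
            make_expression(X.values[:10], genes=X.gene_ids[:10])
        )
        np.testing.assert_allclose(sub.values, direct.values)

    def test_equals_cosine_similarity_of_centered_columns(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(30, 6))
        centered = vals - vals.mean(axis=0, keepdims=True)
        unit = centered / np.linalg.norm(centered, axis=0)
        cos_sim = unit.T @ unit
        rho = np.corrcoef(vals, rowvar=False)
        np.testing.assert_allclose(rho, cos_sim, atol=1e-12)


class TestCosineDistance:
    def test_identical_columns(self):
        X = make_expression(np.tile([[1.0], [2.0]], (1, 2)))
        # arccos near 1 amplifies rounding; zero only to sqrt(eps)
        assert cosine_distance_matrix(X).values[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_orthogonal_columns_map_to_half(self):
        X = make_expression([[1.0, 0.0], [0.0, 1.0]])
        assert cosine_distance_matrix(X).values[0, 1] == pytest.approx(0.5)

    def test_antiparallel_columns_map_to_one(self):
        X = make_expression([[1.0, -1.0], [2.0, -2.0]])
        assert cosine_distance_matrix(X).values[0, 1] == pytest.approx(1.0)

    def test_zero_norm_column_rejected(self):
        X = make_expression([[0.0, 1.0], [0.0, 2.0]], samples=["null", "ok"])
        with pytest.raises(ValueError, match="null"):
            cosine_distance_matrix(X)


class TestHammingDistance:
    @pytest.fixture
    def cat(self):
        values = np.array([["A", "A"], ["A", "B"], ["B", "B"]], dtype=object)
        return CategoricalMatrix(values, ["g1", "g2", "g3"], ["s1", "s2"])

    def test_one_of_three_mismatches(self, cat):
        assert hamming_distance_matrix(cat).values[0, 1] == pytest.approx(1 / 3)

    def test_raw_counts_scale_by_length(self, cat):
        D = hamming_distance_matrix(cat, normalized=False)
        assert D.values[0, 1] == pytest.approx(1.0)

    def test_identical_and_fully_mismatching_columns(self):
        same = CategoricalMatrix(
            np.array([[0, 0], [1, 1]]), ["g1", "g2"], ["a", "b"], alphabet=(0, 1)
        )
        diff = CategoricalMatrix(
            np.array([[0, 1], [1, 0]]), ["g1", "g2"], ["a", "b"], alphabet=(0, 1)
        )
        assert hamming_distance_matrix(same).values[0, 1] == 0.0
        assert hamming_distance_matrix(diff).values[0, 1] == 1.0


class TestDistanceMatrixInvariants:
    def test_asymmetric_input_rejected(self):
        vals = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(vals, ["a", "b"])

    def test_negative_and_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(np.array([[0.0, -1.0], [-1.0, 0.0]]), ["a", "b"])
        with pytest.raises(ValueError):
            DistanceMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]), ["a", "b"])

    @pytest.mark.parametrize("metric_seed", range(5))
    def test_expression_metrics_produce_valid_distance_matrices(self, metric_seed):
        rng = np.random.default_rng(metric_seed)
        X = make_expression(rng.normal(8, 1, size=(25, 8)))
        for D in (pearson_distance_matrix(X), cosine_distance_matrix(X)):
            assert np.all(D.values >= 0)
            assert np.all(D.values <= 1 + 1e-12)
            np.testing.assert_allclose(D.values, D.values.T)
            assert np.all(np.diag(D.values) == 0)


class TestDispersionDistances:
    def test_all_zero_distances_give_zero_dispersion(self):
        D = DistanceMatrix(np.zeros((4, 4)), list("abcd"))
        res = dispersion_distances(D)
        np.testing.assert_array_equal(res.per_sample_distance, np.zeros(4))

    def test_planar_triangle_matches_coordinate_centroid(self):
        points = [(0.0, 0.0), (2.0, 0.0), (0.0, 2.0)]
        res = dispersion_distances(euclidean_dm(points))
        np.testing.assert_allclose(
            res.per_sample_distance, centroid_distances(points), atol=1e-10
        )
        # the printed reference values for this configuration
        np.testing.assert_allclose(
            res.per_sample_distance, [0.9428, 1.4907, 1.4907], atol=1e-4
        )

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("dim", [2, 3])
    def test_euclidean_input_recovers_direct_centroid_distances(self, seed, dim):
        rng = np.random.default_rng(seed)
        points = rng.normal(size=(rng.integers(3, 12), dim))
        res = dispersion_distances(euclidean_dm(points))
        np.testing.assert_allclose(
            res.per_sample_distance, centroid_distances(points), atol=1e-8
        )

    def test_matches_scikit_bio_principal_coordinate_embedding(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        points = rng.normal(size=(9, 3))
        dm = euclidean_dm(points)
        ours = dispersion_distances(dm).per_sample_distance
        coords = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.values, dm.sample_ids)
        ).samples.to_numpy()
        theirs = np.linalg.norm(coords - coords.mean(axis=0), axis=1)
        np.testing.assert_allclose(ours, theirs, atol=1e-8)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_gower_diagonal_identity_for_arbitrary_distance_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 10))
        d = rng.uniform(0, 1, size=(n, n))
        d = np.triu(d, k=1)
        d = d + d.T
        # independent double-centering oracle: explicit J (-1/2 D^2) J
        j = np.eye(n) - np.ones((n, n)) / n
        g_oracle = j @ (-0.5 * d * d) @ j
        np.testing.assert_allclose(gower_center(d), g_oracle, atol=1e-10)
        res = dispersion_distances(DistanceMatrix(d, [f"s{i}" for i in range(n)]))
        np.testing.assert_allclose(
            res.per_sample_distance**2,
            np.clip(np.diag(g_oracle), 0.0, None),
            atol=1e-10,
        )
        # conservation identity of Gower centering
        assert np.mean(np.diag(g_oracle)) == pytest.approx(
            (d**2).sum() / (2 * n**2), abs=1e-10
        )

    def test_semimetric_input_reports_negative_eigenvalues(self):
        # a distance matrix violating the Euclidean embedding condition
        d = np.array(
            [
                [0.0, 1.0, 1.0, 1.0],
                [1.0, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.05],
                [1.0, 1.0, 0.05, 0.0],
            ]
        )
        res = dispersion_distances(DistanceMatrix(d, list("abcd")))
        assert res.n_negative_eigenvalues >= 0
        assert len(res.eigenvalues) == 4
        assert np.all(res.per_sample_distance >= 0)

    def test_literal_centering_is_a_distinct_diagnostic(self):
        points = [(0.0, 0.0), (2.0, 0.0), (0.0, 2.0)]
        dm = euclidean_dm(points)
        gower = dispersion_distances(dm, centering="gower")
        literal = dispersion_distances(dm, centering="literal")
        assert not np.allclose(
            gower.per_sample_distance, literal.per_sample_distance
        )


class TestSummarizeDiversity:
    def test_distance_matrix_uses_unique_offdiagonal_entries(self):
        vals = np.array(
            [[0.0, 0.2, 0.4], [0.2, 0.0, 0.6], [0.4, 0.6, 0.0]]
        )
        D = DistanceMatrix(vals, list("abc"))
        assert summarize_diversity(D, "mean") == pytest.approx(0.4)
        assert summarize_diversity(D, "median") == pytest.approx(0.4)

    def test_vector_summaries(self):
        assert summarize_diversity([0.0, 1.0, 2.0], "mean") == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_diversity([])

    def test_unknown_stat_rejected(self):
        with pytest.raises(ValueError):
            summarize_diversity([1.0], stat="mode")


class TestFilterExpression:
    def test_quartile_then_mad_decile_counts(self):
        rng = np.random.default_rng(0)
        n = 100
        means = np.arange(n, dtype=float)
        spreads = 1.0 + rng.permutation(n) / 10.0  # distinct MADs
        vals = means[:, None] + spreads[:, None] * np.array([-1.0, 0.0, 0.0, 1.0])
        X = make_expression(vals)
        out = filter_expression(X)
        # 25 genes fall strictly below the mean quartile, then 8 of the
        # remaining 75 fall strictly below the MAD decile cutoff
        assert out.n_genes == 67
        assert out.metadata["filter"]["n_genes_out"] == 67

    def test_zero_quantiles_are_identity(self, small_cohort):
        out = filter_expression(small_cohort, 0.0, 0.0)
        assert out.gene_ids == small_cohort.gene_ids

    def test_four_gene_toy_drops_lowest_mean(self):
        vals = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]])
        vals = vals + np.array([[0.0, 0.1]] * 4) * np.arange(1, 5)[:, None]
        X = make_expression(vals, genes=["low", "b", "c", "d"])
        out = filter_expression(X, low_expr_quantile=0.25, low_mad_quantile=0.0)
        assert "low" not in out.gene_ids
        assert out.n_genes == 3

    def test_invalid_quantiles_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            filter_expression(small_cohort, low_expr_quantile=1.0)
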