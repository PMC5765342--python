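"""Similarity computation and collaborative-filtering completion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenorec import (
    AlignmentError,
    RatingMatrix,
    SimilarityMatrix,
    cosine_similarity,
    ibcf_complete,
    ibcf_predict_cell,
    item_similarity_matrix,
    pearson_similarity,
    ubcf_complete,
)
from conftest import random_rating_matrix


def naive_eq1_predict(values, mask, W, i, jprime):
    """Independent double-loop weighted average over the row's rated items."""
    num = den = 0.0
    m = values.shape[1]
    for j in range(m):
        if j == jprime or not mask[i, j] or not np.isfinite(W[j, jprime]):
            continue
        num += values[i, j] * W[j, jprime]
        den += abs(W[j, jprime])
    if den == 0:
        return np.nan
    return num / den


class TestPairwiseSimilarity:
    def test_cosine_self_similarity_is_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cosine_similarity(x, x) == pytest.approx(1.0)

    def test_cosine_orthogonal_vectors(self):
        assert cosine_similarity(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_cosine_pairwise_complete_toy_items(self):
        # items I2 and I3 share only users U3 and U4
        i2 = np.array([np.nan, 2.0, 3.0, 2.0])
        i3 = np.array([3.0, np.nan, 1.0, 2.0])
        expected = (3 * 1 + 2 * 2) / (np.sqrt(13) * np.sqrt(5))
        assert cosine_similarity(i2, i3) == pytest.approx(expected)
        assert cosine_similarity(i2, i3) == pytest.approx(0.8682, abs=5e-5)

    def test_cosine_undefined_below_min_overlap(self):
        x = np.array([1.0, np.nan, np.nan])
        y = np.array([2.0, 1.0, np.nan])
        assert np.isnan(cosine_similarity(x, y, min_overlap=2))

    def test_pearson_perfect_linear(self):
        r = pearson_similarity(np.array([1.0, 2, 3]), np.array([2.0, 4, 6]))
        assert r == pytest.approx(1.0, abs=1e-12)
        r = pearson_similarity(np.array([1.0, 2, 3]), np.array([3.0, 2, 1]))
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_pearson_hand_computed(self):
        # r = (24/9) / sqrt((42/9)(24/9)) = 0.755929
        r = pearson_similarity(np.array([1.0, 2, 4]), np.array([1.0, 3, 3]))
        assert r == pytest.approx(0.7559, abs=5e-5)
        assert r == pytest.approx(np.corrcoef([1, 2, 4], [1, 3, 3])[0, 1])

    def test_pearson_zero_variance_undefined(self):
        assert np.isnan(pearson_similarity(np.array([1.0, 1, 1]), np.array([1.0, 2, 3])))


class TestItemSimilarityMatrix:
    def test_toy_matrix_pairwise_complete_cosine_entries(self, toy_ratings):
        S = item_similarity_matrix(toy_ratings, method="cosine")
        assert S.weights[0, 2] == pytest.approx(0.7894, abs=5e-5)
        assert S.weights[1, 2] == pytest.approx(0.8682, abs=5e-5)
        assert S.overlap[1, 2] == 2

    def test_duplicate_columns_have_unit_weight(self):
        values = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        R = RatingMatrix(["a", "b", "c"], ["E1_T1", "E1_T2"], values, np.ones((3, 2), bool))
        S = item_similarity_matrix(R)
        assert S.weights[0, 1] == pytest.approx(1.0)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_symmetry_and_boundedness(self, seed):
        rng = np.random.default_rng(seed)
        R = random_rating_matrix(rng)
        S = item_similarity_matrix(R, method="cosine")
        np.testing.assert_array_equal(np.isfinite(S.weights), np.isfinite(S.weights.T))
        defined = np.isfinite(S.weights)
        np.testing.assert_allclose(S.weights[defined], S.weights.T[defined])
        assert np.all(np.abs(S.weights[defined]) <= 1 + 1e-12)
        np.testing.assert_array_equal(S.overlap, S.overlap.T)


class TestIBCF:
    def test_worked_example_predictions(self, toy_ratings, toy_similarity):
        p12 = ibcf_predict_cell(toy_ratings, toy_similarity, 0, 1)
        p23 = ibcf_predict_cell(toy_ratings, toy_similarity, 1, 2)
        p41 = ibcf_predict_cell(toy_ratings, toy_similarity, 3, 0)
        assert round(p12, 2) == 2.53
        assert round(p23, 2) == 3.43
        assert round(p41, 2) == 2.0

    def test_constant_row_predicts_constant(self):
        values = np.array([[4.0, 4.0, np.nan]])
        R = RatingMatrix(["g"], ["E1_T1", "E1_T2", "E1_T3"], values, np.isfinite(values))
        W = np.array([[1, 0.5, 0.3], [0.5, 1, 0.7], [0.3, 0.7, 1.0]])
        S = SimilarityMatrix(R.col_ids, W, np.ones((3, 3), int), "external")
        assert ibcf_predict_cell(R, S, 0, 2) == pytest.approx(4.0)

    def test_completion_contains_worked_example_values(self, toy_ratings, toy_similarity):
        completed, fallback = ibcf_complete(toy_ratings, similarity=toy_similarity)
        assert fallback == []
        assert round(completed.values[0, 1], 2) == 2.53
        assert round(completed.values[1, 2], 2) == 3.43
        assert round(completed.values[3, 0], 2) == 2.0
        # observed cells untouched
        np.testing.assert_array_equal(
            completed.values[toy_ratings.mask], toy_ratings.values[toy_ratings.mask]
        )

    def test_fully_observed_matrix_returned_unchanged(self):
        values = np.arange(6.0).reshape(2, 3) + 1
        R = RatingMatrix(["a", "b"], ["E1_T1", "E1_T2", "E1_T3"], values, np.ones((2, 3), bool))
        completed, fallback = ibcf_complete(R)
        np.testing.assert_array_equal(completed.values, values)
        assert fallback == []

    def test_zero_denominator_falls_back_to_column_mean(self):
        values = np.array([[1.0, np.nan], [2.0, 3.0], [4.0, 5.0]])
        W = np.array([[1.0, 0.0], [0.0, 1.0]])  # no cross-item information
        R = RatingMatrix(["a", "b", "c"], ["E1_T1", "E1_T2"], values, np.isfinite(values))
        S = SimilarityMatrix(R.col_ids, W, np.full((2, 2), 3, int), "external")
        completed, fallback = ibcf_complete(R, similarity=S)
        assert fallback == [("a", "E1_T2")]
        assert completed.values[0, 1] == pytest.approx(4.0)  # mean of {3, 5}

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_eq1(self, seed):
        rng = np.random.default_rng(seed)
        R = random_rating_matrix(rng)
        S = item_similarity_matrix(R, method="cosine")
        completed, _ = ibcf_complete(R, similarity=S)
        for i, j in zip(*np.where(~R.mask)):
            expected = naive_eq1_predict(R.values, R.mask, S.weights, i, j)
            if np.isfinite(expected):
                assert completed.values[i, j] == pytest.approx(expected, abs=1e-10)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_prediction_bounded_by_row_ratings_for_nonnegative_weights(self, seed):
        rng = np.random.default_rng(seed)
        R = random_rating_matrix(rng)
        S = item_similarity_matrix(R, method="cosine")
        for i, j in zip(*np.where(~R.mask)):
            pred = ibcf_predict_cell(R, S, i, j, neighborhood="nonnegative")
            if np.isfinite(pred):
                obs = R.values[i, R.mask[i]]
                assert obs.min() - 1e-10 <= pred <= obs.max() + 1e-10

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_completion_invariant_to_permutation(self, seed):
        rng = np.random.default_rng(seed)
        R = random_rating_matrix(rng)
        completed, _ = ibcf_complete(R)
        rp = rng.permutation(R.n_rows)
        cp = rng.permutation(R.n_cols)
        Rp = RatingMatrix(
            [R.row_ids[i] for i in rp],
            [R.col_ids[j] for j in cp],
            R.values[np.ix_(rp, cp)],
            R.mask[np.ix_(rp, cp)],
        )
        completed_p, _ = ibcf_complete(Rp)
        np.testing.assert_allclose(
            completed_p.values, completed.values[np.ix_(rp, cp)], atol=1e-12
        )


class TestUBCF:
    def test_transpose_duality_with_ibcf(self, toy_ratings, toy_similarity):
        completed_u, _ = ubcf_complete(toy_ratings.transposed(), user_similarity=toy_similarity)
        completed_i, _ = ibcf_complete(toy_ratings, similarity=toy_similarity)
        np.testing.assert_allclose(completed_u.values.T, completed_i.values, atol=1e-12)

    def test_identity_similarity_falls_back_to_column_means(self, toy_ratings):
        S = SimilarityMatrix(
            toy_ratings.row_ids, np.eye(4), np.full((4, 4), 3, int), "external"
        )
        completed, fallback = ubcf_complete(toy_ratings, user_similarity=S)
        assert len(fallback) == 3
        # missing (U1, I2) falls back to the observed mean of column I2
        assert completed.values[0, 1] == pytest.approx(np.mean([2, 3, 2]))

    def test_id_mismatch_raises_alignment_error(self, toy_ratings):
        S = SimilarityMatrix(["x1", "x2", "x3", "x4"], np.eye(4), np.eye(4, dtype=int), "external")
        with pytest.raises(AlignmentError, match="x1"):
            ubcf_complete(toy_ratings, user_similarity=S)

    def test_compound_symmetric_similarity_matches_brute_force(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(5, 3))
        mask = np.ones((5, 3), bool)
        mask[0, 1] = mask[3, 2] = mask[4, 0] = False
        values[~mask] = np.nan
        R = RatingMatrix(
            [f"g{i}" for i in range(5)], [f"E1_T{j}" for j in range(3)], values, mask
        )
        W = 0.7 * np.eye(5) + 0.3 * np.ones((5, 5))
        S = SimilarityMatrix(R.row_ids, W, np.full((5, 5), 3, int), "external")
        completed, _ = ubcf_complete(R, user_similarity=S)
        vt, mt = values.T, mask.T
        for i, j in zip(*np.where(~mask)):
            expected = naive_eq1_predict(vt, mt, W, j, i)
            assert completed.values[i, j] == pytest.approx(expected, abs=1e-10)

    def test_similarity_permutation_alignment(self, toy_ratings):
        # similarity rows given in a different genotype order must be realigned
        order = [2, 0, 3, 1]
        ids = [toy_ratings.row_ids[i] for i in order]
        W = 1.0 / (1.0 + np.abs(np.subtract.outer(np.arange(4), np.arange(4))))
        S = SimilarityMatrix(toy_ratings.row_ids, W, np.full((4, 4), 3, int), "external")
        S_perm = SimilarityMatrix(
            ids, W[np.ix_(order, order)], np.full((4, 4), 3, int), "external"
        )
        a, _ = ubcf_complete(toy_ratings, user_similarity=S_perm)
        b, _ = ubcf_complete(toy_ratings, user_similarity=S)
        np.testing.assert_allclose(a.values, b.values)
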