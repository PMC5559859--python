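import numpy as np
import pytest

from ancut.graph import (DegenerateSimilarityError, ancut_objective, cut_value,
                         cutvol_value, exhaustive_minimizer, ncut_objective,
                         rescale_similarity, similarity_matrix)
from conftest import brute_force_cut, brute_force_cutvol, brute_force_objective

SQRT10 = np.sqrt(10.0)


class TestSimilarity:
    def test_hand_computed_inverse_distances(self, four_gene_similarity):
        W = four_gene_similarity
        assert W[0, 1] == pytest.approx(1.0)
        assert W[2, 3] == pytest.approx(1.0)
        assert W[0, 2] == pytest.approx(1.0 / 3.0)
        assert W[0, 3] == pytest.approx(1.0 / SQRT10)
        assert W[1, 2] == pytest.approx(1.0 / SQRT10)

    def test_symmetric_zero_diagonal_nonnegative(self):
        rng = np.random.default_rng(0)
        W = similarity_matrix(rng.normal(size=(8, 15)))
        assert np.allclose(W, W.T)
        assert np.all(np.diag(W) == 0.0)
        assert np.all(W >= 0.0) and np.all(np.isfinite(W))

    def test_duplicate_columns_capped_finite(self):
        M = np.array([[1.0, 1.0, 4.0], [2.0, 2.0, 0.0]])
        W = similarity_matrix(M)
        assert np.isfinite(W[0, 1])
        # the cap is 1 / (scale * median positive distance)
        d = np.sqrt(3.0**2 + 2.0**2)
        assert W[0, 1] == pytest.approx(1.0 / (1e-12 * d))

    def test_all_identical_columns_rejected(self):
        with pytest.raises(DegenerateSimilarityError):
            similarity_matrix(np.ones((3, 4)))

    def test_rescale_unit_mean_offdiagonal(self, four_gene_similarity):
        W = rescale_similarity(four_gene_similarity)
        p = W.shape[0]
        assert W.sum() / (p * (p - 1)) == pytest.approx(1.0)


class TestCutAndVolume:
    def test_single_cluster_has_zero_cut(self, four_gene_similarity):
        labels = np.zeros(4, dtype=int)
        assert cut_value(labels, 0, four_gene_similarity) == 0.0

    def test_toy_cut_value_and_brute_force(self, four_gene_similarity):
        labels = np.array([0, 0, 1, 1])
        expected = 2.0 / 3.0 + 2.0 / SQRT10
        got = cut_value(labels, 0, four_gene_similarity)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(
            brute_force_cut(labels, 0, four_gene_similarity))

    def test_cut_is_linear_in_w(self, four_gene_similarity):
        labels = np.array([0, 0, 1, 1])
        assert cut_value(labels, 0, 2.0 * four_gene_similarity) == \
            pytest.approx(2.0 * cut_value(labels, 0, four_gene_similarity))

    def test_singleton_cluster_has_zero_volume(self, four_gene_similarity):
        labels = np.array([0, 1, 1, 1])
        assert cutvol_value(labels, 0, four_gene_similarity) == 0.0

    def test_toy_cutvol_ordered_pairs(self, four_gene_similarity):
        labels = np.array([0, 0, 1, 1])
        got = cutvol_value(labels, 0, four_gene_similarity)
        assert got == pytest.approx(2.0)  # 2 * w12
        assert got == pytest.approx(
            brute_force_cutvol(labels, 0, four_gene_similarity))

    def test_full_set_volume_is_total_offdiagonal_mass(self, four_gene_similarity):
        labels = np.zeros(4, dtype=int)
        assert cutvol_value(labels, 0, four_gene_similarity) == \
            pytest.approx(four_gene_similarity.sum())


class TestObjectives:
    def test_one_cluster_objective_is_zero(self, four_gene_similarity):
        assert ancut_objective(np.zeros(4, dtype=int), four_gene_similarity,
                               four_gene_similarity) == 0.0

    def test_toy_value_against_brute_force(self, four_gene_similarity):
        labels = np.array([0, 0, 1, 1])
        W = four_gene_similarity
        expected = 2.0 * (2.0 / 3.0 + 2.0 / SQRT10) / 2.0
        assert ancut_objective(labels, W, W) == pytest.approx(expected)
        assert ancut_objective(labels, W, W) == pytest.approx(
            brute_force_objective(labels, W, W))

    def test_singleton_gives_infinity(self, four_gene_similarity):
        labels = np.array([0, 1, 1, 1])
        assert ancut_objective(labels, four_gene_similarity,
                               four_gene_similarity) == np.inf

    def test_ncut_equals_ancut_with_same_matrix(self, four_gene_similarity):
        labels = np.array([0, 1, 0, 1])
        assert ncut_objective(labels, four_gene_similarity) == \
            ancut_objective(labels, four_gene_similarity, four_gene_similarity)

    def test_label_relabeling_invariance(self, four_gene_similarity):
        W = four_gene_similarity
        labels = np.array([0, 0, 1, 1])
        flipped = 1 - labels
        assert ncut_objective(labels, W) == pytest.approx(
            ncut_objective(flipped, W))

    def test_consistent_gene_permutation_invariance(self):
        rng = np.random.default_rng(3)
        M = rng.normal(size=(6, 9))
        W = similarity_matrix(M)
        Wh = similarity_matrix(M + rng.normal(scale=0.1, size=M.shape))
        labels = rng.integers(0, 2, size=9)
        labels[0], labels[1] = 0, 1
        perm = rng.permutation(9)
        assert ancut_objective(labels, W, Wh) == pytest.approx(
            ancut_objective(labels[perm], W[np.ix_(perm, perm)],
                            Wh[np.ix_(perm, perm)]))

    def test_scaling_behaviour(self, four_gene_similarity):
        W = four_gene_similarity
        labels = np.array([0, 0, 1, 1])
        base = ancut_objective(labels, W, W)
        assert ancut_objective(labels, 3.0 * W, W) == pytest.approx(3.0 * base)
        assert ancut_objective(labels, W, 3.0 * W) == pytest.approx(base / 3.0)

    def test_nonnegative_zero_iff_no_cross_mass(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        labels = np.array([0, 0, 1, 1])
        assert ncut_objective(labels, W) == 0.0


class TestExhaustiveMinimizer:
    def test_toy_partition_is_global_minimum(self, four_gene_similarity):
        W = four_gene_similarity
        labels, value = exhaustive_minimizer(W, W, 2)
        assert np.array_equal(labels, [0, 0, 1, 1])
        # verify against enumeration of all 7 bipartitions by brute force
        values = []
        for mask in range(1, 7 + 1):
            lab = np.array([(mask >> i) & 1 for i in range(4)])
            if len(np.unique(lab)) == 2:
                values.append(brute_force_objective(lab, W, W))
        assert value == pytest.approx(min(values))

    def test_k_equals_one_trivial(self, four_gene_similarity):
        labels, value = exhaustive_minimizer(four_gene_similarity,
                                             four_gene_similarity, 1)
        assert np.array_equal(labels, np.zeros(4, dtype=int))
        assert value == 0.0

    def test_all_singletons_infinite(self, four_gene_similarity):
        _, value = exhaustive_minimizer(four_gene_similarity,
                                        four_gene_similarity, 4)
        assert value == np.inf

    def test_guard_on_large_p(self):
        W = np.zeros((15, 15))
        with pytest.raises(ValueError):
            exhaustive_minimizer(W, W, 2)
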