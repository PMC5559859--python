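import numpy as np
import pytest

from ancut.anneal import (SAConfig, acceptance_step, anneal,
                          pair_count_weights, propose_move, temperature)
from ancut.graph import (ancut_objective, exhaustive_minimizer,
                         similarity_matrix)
from conftest import brute_force_objective


class TestTemperature:
    def test_printed_formula(self):
        cfg = SAConfig(schedule="printed", L=1000.0)
        assert temperature(1, cfg) == pytest.approx(1000.0 * np.log(2.0))

    def test_cooling_decreases_to_zero(self):
        cfg = SAConfig(schedule="cooling", L=1000.0)
        temps = [temperature(t, cfg) for t in (1, 10, 100, 10_000, 10**7)]
        assert all(a > b for a, b in zip(temps, temps[1:]))
        assert temps[-1] < 1e-4

    def test_positive_for_all_t(self):
        for schedule in ("cooling", "printed"):
            cfg = SAConfig(schedule=schedule)
            assert min(temperature(t, cfg) for t in (1, 2, 5, 999)) > 0

    def test_rejects_t_below_one(self):
        with pytest.raises(ValueError):
            temperature(0, SAConfig())


class TestProposeMove:
    def test_smoothed_pair_weights(self):
        # sizes {3,1}: within-pair counts (3,0), smoothed (4,1) -> raw law 4/5
        w = pair_count_weights(np.array([3, 1]))
        assert np.allclose(w, [4.0, 1.0])
        assert w[0] / w.sum() == pytest.approx(4.0 / 5.0)

    def test_singleton_never_selected_as_source(self):
        labels = np.array([0, 0, 0, 1])
        rng = np.random.default_rng(0)
        for _ in range(200):
            k_minus, k_plus, gene = propose_move(labels, 2, rng)
            assert k_minus == 0 and k_plus == 1
            assert labels[gene] == 0

    def test_empirical_frequencies_match_law(self):
        # sizes {3,2}: source weights (C(3,2)+1, C(2,2)+1) = (4, 2) -> 2/3, 1/3
        labels = np.array([0, 0, 0, 1, 1])
        rng = np.random.default_rng(123)
        n = 30_000
        draws = np.array([propose_move(labels, 2, rng)[0] for _ in range(n)])
        freq = (draws == 0).mean()
        se = np.sqrt((2 / 3) * (1 / 3) / n)
        assert abs(freq - 2.0 / 3.0) < 3.0 * se

    def test_gene_uniform_within_source(self):
        labels = np.array([0, 0, 0, 1, 1])
        rng = np.random.default_rng(7)
        genes = [propose_move(labels, 2, rng)[2] for _ in range(6000)]
        genes = np.array(genes)
        for g in (0, 1, 2):
            share = (genes == g).mean() / (labels[genes] == 0).mean()
            assert share == pytest.approx(1.0 / 3.0, abs=0.03)

    def test_all_singletons_rejected(self):
        with pytest.raises(ValueError):
            propose_move(np.array([0, 1, 2]), 3, np.random.default_rng(0))


class TestAcceptance:
    def test_improvement_and_tie_always_accepted(self):
        cfg = SAConfig()
        rng = np.random.default_rng(0)
        assert acceptance_step(1.0, 0.5, 1, cfg, rng)
        assert acceptance_step(1.0, 1.0, 1, cfg, rng)

    def test_infinite_proposal_rejected(self):
        assert not acceptance_step(1.0, np.inf, 1, SAConfig(),
                                   np.random.default_rng(0))

    def test_delta_equal_temperature_accepts_at_rate_1_over_e(self):
        cfg = SAConfig(L=1000.0)
        rng = np.random.default_rng(99)
        n = 30_000
        t = 50
        delta = temperature(t, cfg)
        hits = sum(acceptance_step(1.0, 1.0 + delta, t, cfg, rng)
                   for _ in range(n))
        target = np.exp(-1.0)
        se = np.sqrt(target * (1 - target) / n)
        assert abs(hits / n - target) < 3.0 * se


def random_instance(p, seed, structured=False):
    rng = np.random.default_rng(seed)
    if structured:
        centers = np.repeat([[-2.0], [2.0]], p // 2, axis=0)
        M = (centers + 0.3 * rng.normal(size=(p, 12))).T
    else:
        M = rng.normal(size=(12, p))
    return similarity_matrix(M)


class TestAnneal:
    def test_attains_exhaustive_minimum_small_p(self):
        W = random_instance(8, 5)
        Wh = random_instance(8, 6)
        _, best = exhaustive_minimizer(W, Wh, 2)
        # L matched to the O(0.1-1) objective deltas of raw small instances
        labels, trace = anneal(W, Wh, SAConfig(K=2, B=5000, L=0.5, seed=1))
        assert trace.best_value == pytest.approx(best, rel=1e-10)

    def test_separable_instance_recovers_blocks(self):
        # W-hat with two perfect blocks, W with weak cross mass
        p = 10
        truth = np.repeat([0, 1], p // 2)
        Wh = np.where(truth[:, None] == truth[None, :], 1.0, 0.0)
        np.fill_diagonal(Wh, 0.0)
        rng = np.random.default_rng(2)
        W = np.abs(rng.normal(scale=0.05, size=(p, p)))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        labels, _ = anneal(W, Wh, SAConfig(K=2, B=4000, seed=3))
        assert len(np.unique(labels[:5])) == 1
        assert len(np.unique(labels[5:])) == 1
        assert labels[0] != labels[-1]

    def test_budget_of_one_gives_unit_trace(self):
        W = random_instance(6, 9)
        _, trace = anneal(W, W, SAConfig(K=2, B=1, seed=0))
        assert trace.objective_sequence.shape == (1,)

    def test_reproducible_given_seed(self):
        W = random_instance(9, 11)
        la, ta = anneal(W, W, SAConfig(K=3, B=2000, seed=4))
        lb, tb = anneal(W, W, SAConfig(K=3, B=2000, seed=4))
        assert np.array_equal(la, lb)
        assert np.array_equal(ta.objective_sequence, tb.objective_sequence)

    def test_best_envelope_monotone_in_budget(self):
        W = random_instance(9, 13)
        values = [anneal(W, W, SAConfig(K=2, B=b, seed=7))[1].best_value
                  for b in (200, 1000, 5000)]
        assert values[0] >= values[1] >= values[2]

    def test_incremental_objective_matches_full_recomputation(self):
        W = random_instance(10, 17)
        Wh = random_instance(10, 18)
        labels, trace = anneal(W, Wh, SAConfig(K=2, B=1500, seed=5))
        # the accumulated incremental value of the final state agrees with a
        # from-scratch evaluation (B < resync interval, so purely incremental)
        assert trace.objective_sequence[-1] == pytest.approx(
            ancut_objective(trace.final_labels, W, Wh), rel=1e-8)
        # best value always equals an exact recomputation on best labels
        assert trace.best_value == pytest.approx(
            brute_force_objective(trace.best_labels, W, Wh), rel=1e-10)

    def test_different_initializations_agree_on_strong_signal(self):
        W = random_instance(12, 19, structured=True)
        finals = []
        for seed in range(4):
            labels, _ = anneal(W, W, SAConfig(K=2, B=4000, seed=seed))
            if labels[0] == 1:
                labels = 1 - labels
            finals.append(labels)
        for other in finals[1:]:
            assert np.array_equal(finals[0], other)

    def test_rejects_more_clusters_than_genes(self):
        W = random_instance(4, 1)
        with pytest.raises(ValueError):
            anneal(W, W, SAConfig(K=5, B=10, seed=0))
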