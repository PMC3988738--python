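import numpy as np
import pytest
from scipy import stats
from sklearn.base import clone

import trigen3d.ga as ga
from trigen3d import (ExpressionTensor3D, SolutionSet, TriGen, TriGenParams,
                      Tricluster, crossover, evolve_one, fitness,
                      init_population, msr3d, mutate, run_trigen, select)


def params(**kw):
    base = dict(n_solutions=2, n_generations=5, n_individuals=20, seed=0)
    base.update(kw)
    return TriGenParams(**base)


class TestFitness:
    def test_zero_weights_reduce_to_normalised_msr(self, small_tensor,
                                                   full_tricluster):
        p = params(w_g=0, w_c=0, w_t=0, wo_g=0, wo_c=0, wo_t=0)
        fb = fitness(small_tensor, full_tricluster, p)
        expected = (msr3d(small_tensor, full_tricluster)
                    / small_tensor.value_range() ** 2)
        assert fb.ff == pytest.approx(expected)
        assert fb.size_reward == 0 and fb.overlap_reward == 0

    def test_constant_tensor_full_gene_cluster(self, constant_tensor):
        tc = Tricluster(range(4), [0, 1], [0, 1])
        p = params(w_g=1.0, w_c=0, w_t=0, wo_g=0, wo_c=0, wo_t=0)
        fb = fitness(constant_tensor, tc, p)
        assert fb.ff == pytest.approx(-1.0)

    def test_gene_weight_rewards_gene_rich_clusters(self, small_tensor):
        small = Tricluster([0, 1], [0, 1], [0, 1])
        big = Tricluster(range(8), [0, 1], [0, 1])
        lo, hi = (params(w_g=w, w_c=0, w_t=0) for w in (0.0, 1.0))
        gain_small = (fitness(small_tensor, small, lo).ff
                      - fitness(small_tensor, small, hi).ff)
        gain_big = (fitness(small_tensor, big, lo).ff
                    - fitness(small_tensor, big, hi).ff)
        assert gain_big > gain_small > 0

    def test_overlap_reward_vanishes_on_fully_used_indices(self, small_tensor,
                                                           full_tricluster):
        prior = SolutionSet()
        prior.append(full_tricluster,
                     fitness(small_tensor, full_tricluster, params()))
        fb = fitness(small_tensor, full_tricluster, params(), prior)
        assert fb.overlap_reward == 0.0

    def test_unnormalised_mode(self, small_tensor, full_tricluster):
        p = params(w_g=0, w_c=0, w_t=0, wo_g=0, wo_c=0, wo_t=0,
                   normalize_msr=False)
        fb = fitness(small_tensor, full_tricluster, p)
        assert fb.msr3d_term == pytest.approx(
            msr3d(small_tensor, full_tricluster))


class TestInitPopulation:
    def test_population_size_and_floors(self, small_tensor, rng):
        p = params(n_individuals=37, min_genes=3, min_conditions=2,
                   min_times=2)
        pop = init_population(small_tensor, p, None, rng)
        assert len(pop) == 37
        for ind in pop:
            assert ind.shape >= (3, 2, 2)

    def test_all_random_at_ale_one(self, small_tensor, rng):
        pop = init_population(small_tensor, params(ale=1.0, n_individuals=30),
                              None, rng)
        assert len(pop) == 30

    def test_saturated_prior_degrades_to_uniform(self, small_tensor, rng):
        prior = SolutionSet()
        full = Tricluster(range(8), range(5), range(4))
        prior.append(full, fitness(small_tensor, full, params()))
        pop = init_population(small_tensor, params(ale=0.0), prior, rng)
        assert len(pop) == params().n_individuals

    def test_floors_exceeding_extents_raise(self, small_tensor, rng):
        with pytest.raises(ValueError, match="exceed"):
            init_population(small_tensor, params(min_genes=100), None, rng)


class TestSelect:
    def test_single_individual_always_survives(self, rng):
        ind = Tricluster([0], [0], [0])
        out = select([ind], [0.5], params(sel=1.0), rng)
        assert out == [ind]

    def test_equal_fitness_selection_is_uniform(self, rng):
        pop = [Tricluster([i], [0], [0]) for i in range(5)]
        counts = np.zeros(5)
        p = params(sel=0.2)  # one survivor per draw
        for _ in range(4000):
            chosen = select(pop, [1.0] * 5, p, rng)
            counts[chosen[0].genes[0]] += 1
        assert stats.chisquare(counts).pvalue > 0.01

    def test_lower_ff_is_selected_more_often(self, rng):
        pop = [Tricluster([0], [0], [0]), Tricluster([1], [0], [0])]
        wins = 0
        p = params(sel=0.5)
        for _ in range(2000):
            chosen = select(pop, [0.1, 0.9], p, rng)
            wins += chosen[0].genes[0] == 0
        assert wins > 1500

    def test_misaligned_fitnesses_raise(self, rng):
        with pytest.raises(ValueError, match="aligned"):
            select([Tricluster([0], [0], [0])], [1.0, 2.0], params(), rng)


class TestCrossover:
    def test_identical_parents_produce_identical_children(self, rng):
        parent = Tricluster([1, 4, 6], [0, 2], [1, 3])
        c1, c2 = crossover(parent, parent, rng)
        assert c1 == parent and c2 == parent

    def test_children_conserve_parent_material(self, rng):
        a = Tricluster([0, 2, 4], [0, 1], [0, 1, 2])
        b = Tricluster([1, 3, 5, 7], [2, 3], [1, 3])
        for _ in range(50):
            for child in crossover(a, b, rng):
                assert set(child.genes) <= set(a.genes) | set(b.genes)
                assert set(child.conditions) <= (set(a.conditions)
                                                 | set(b.conditions))
                assert set(child.times) <= set(a.times) | set(b.times)

    def test_undersized_children_are_repaired_to_floor(self, rng):
        a = Tricluster([0, 1], [0], [0])
        b = Tricluster([5, 6], [1], [1])
        for _ in range(50):
            for child in crossover(a, b, rng, extents=(10, 4, 4),
                                   min_shape=(2, 1, 1)):
                assert len(child.genes) >= 2


class TestMutate:
    def test_zero_probability_is_identity(self, small_tensor, rng):
        tc = Tricluster([0, 1], [0, 1], [0, 1])
        assert mutate(tc, small_tensor, params(mut=0.0), None, rng) is tc

    def test_certain_mutation_changes_exactly_one_index(self, small_tensor,
                                                        rng):
        p = params(mut=1.0, min_genes=1, min_conditions=1, min_times=1)
        tc = Tricluster([0, 1, 2], [0, 1], [0, 1])
        for _ in range(50):
            out = mutate(tc, small_tensor, p, None, rng)
            diffs = [len(set(a.tolist()) ^ set(b.tolist()))
                     for a, b in ((out.genes, tc.genes),
                                  (out.conditions, tc.conditions),
                                  (out.times, tc.times))]
            assert sorted(diffs) == [0, 0, 1]

    def test_saturated_cluster_with_floors_is_left_unchanged(self, rng):
        # every add hits a full dimension and every removal the floor,
        # so after six re-draws the individual comes back untouched
        tensor = ExpressionTensor3D(np.zeros((2, 2, 2)))
        tc = Tricluster([0, 1], [0, 1], [0, 1])
        p = params(mut=1.0, min_genes=2, min_conditions=2, min_times=2)
        assert mutate(tc, tensor, p, None, rng) == tc


class TestEvolveOne:
    def test_constant_tensor_returns_perfect_cluster(self, constant_tensor,
                                                     rng):
        tc, fb = evolve_one(constant_tensor, params(), None, rng)
        assert msr3d(constant_tensor, tc) == 0.0

    def test_same_seed_is_bit_reproducible(self, small_tensor):
        out = []
        for _ in range(2):
            tc, fb = evolve_one(small_tensor, params(), None,
                                np.random.default_rng(42))
            out.append((tc, fb.ff))
        assert out[0] == out[1]

    def test_population_size_constant_every_generation(self, small_tensor,
                                                       monkeypatch):
        sizes = []
        original = ga.select

        def spy(population, fitnesses, p, rng):
            sizes.append(len(list(population)))
            return original(population, fitnesses, p, rng)

        monkeypatch.setattr(ga, "select", spy)
        evolve_one(small_tensor, params(n_generations=6, n_individuals=15),
                   None, np.random.default_rng(0))
        assert sizes == [15] * 6

    def test_search_beats_random_clusters_on_implanted_signal(self):
        # one additive implant in uniform noise: the best evolved cluster
        # should be more coherent than random clusters of the same shape
        g = np.random.default_rng(5)
        values = g.uniform(0, 100, size=(80, 8, 6))
        alpha = g.uniform(-20, 20, size=16)
        beta = g.uniform(-20, 20, size=4)
        gamma = g.uniform(-20, 20, size=3)
        values[10:26, 2:6, 1:4] = (50 + alpha[:, None, None]
                                   + beta[None, :, None]
                                   + gamma[None, None, :])
        tensor = ExpressionTensor3D(values)
        p = params(n_generations=40, n_individuals=60, ale=0.5,
                   w_g=0, w_c=0, w_t=0, wo_g=0, wo_c=0, wo_t=0,
                   min_genes=4, min_conditions=3, min_times=3)
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            best, fb = evolve_one(tensor, p, None, rng)
            rand = Tricluster(
                np.sort(rng.choice(80, len(best.genes), replace=False)),
                np.sort(rng.choice(8, len(best.conditions), replace=False)),
                np.sort(rng.choice(6, len(best.times), replace=False)))
            wins += msr3d(tensor, best) <= msr3d(tensor, rand)
        assert wins >= 9


class TestRunTriGenAndEstimator:
    def test_returns_requested_number_of_solutions(self, small_tensor):
        sols = run_trigen(small_tensor, params(n_solutions=3))
        assert len(sols) == 3
        for tc in sols:
            assert tc.shape >= params().min_shape()

    def test_estimator_follows_sklearn_protocol(self, small_tensor):
        est = TriGen(n_solutions=2, n_generations=4, n_individuals=10,
                     random_state=7)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est.fit(small_tensor)
        assert len(est.solutions_) == 2
        assert len(est.fitness_) == 2
        assert est.n_genes_in_ == 8

    def test_estimator_accepts_raw_arrays(self, rng):
        X = rng.uniform(0, 1, size=(6, 4, 3))
        est = TriGen(n_solutions=1, n_generations=3, n_individuals=8,
                     random_state=0).fit(X)
        assert len(est.solutions_) == 1

    def test_zero_overlap_weights_make_runs_independent(self, small_tensor):
        # with wo_* = 0 the prior set cannot influence the objective
        p1 = params(n_solutions=1, wo_g=0, wo_c=0, wo_t=0, seed=3)
        single = run_trigen(small_tensor, p1)
        p2 = params(n_solutions=2, wo_g=0, wo_c=0, wo_t=0, seed=3)
        double = run_trigen(small_tensor, p2)
        assert double.triclusters[0] == single.triclusters[0]

    def test_run_trigen_is_deterministic(self, small_tensor):
        a = run_trigen(small_tensor, params(seed=11))
        b = run_trigen(small_tensor, params(seed=11))
        assert a.triclusters == b.triclusters
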