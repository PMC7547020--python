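import numpy as np
import pytest

from radopt.ga import (
    GAConfig,
    Individual,
    breed,
    derive_eval_seed,
    evaluate_individual,
    evolve,
    explored_fraction,
    select_survivors,
    top_k,
)
from radopt.phantoms import hidden_optimum_fitness
from radopt.search_space import FeatureAxis, Genome, SearchSpace, cardinality, random_genome


def _individuals(fitnesses, space, rng):
    out = []
    seen = set()
    while len(out) < len(fitnesses):
        g = random_genome(space, rng)
        if g in seen:
            continue
        seen.add(g)
        out.append(Individual(genome=g, fitness=fitnesses[len(out)]))
    return out


class TestConfigValidation:
    def test_rejects_bad_retention(self):
        with pytest.raises(ValueError):
            GAConfig(retention_rate=0.0)

    def test_rejects_bad_probability(self):
        with pytest.raises(ValueError):
            GAConfig(mutation_prob=1.5)

    def test_rejects_tiny_population(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=1)


class TestEvalSeed:
    def test_depends_only_on_master_seed_and_genome(self, toy_space):
        g = random_genome(toy_space, np.random.default_rng(0))
        assert derive_eval_seed(3, g) == derive_eval_seed(3, g)
        assert derive_eval_seed(3, g) != derive_eval_seed(4, g)
        assert 0 <= derive_eval_seed(3, g) < 2**31

    def test_distinct_genomes_get_distinct_seeds(self, toy_space):
        genomes = list(toy_space.enumerate_genomes())
        seeds = {derive_eval_seed(0, g) for g in genomes}
        assert len(seeds) == len(genomes)


class TestEvaluateIndividual:
    def test_tuple_result_carries_accuracy(self, toy_space):
        g = random_genome(toy_space, np.random.default_rng(0))
        ind = evaluate_individual(g, lambda genome, seed: (0.75, 0.6), 11)
        assert ind.fitness == 0.75 and ind.accuracy == 0.6 and ind.eval_seed == 11

    def test_evaluation_error_becomes_zero_fitness(self, toy_space):
        g = random_genome(toy_space, np.random.default_rng(0))

        def boom(genome, seed):
            raise RuntimeError("fold collapsed")

        ind = evaluate_individual(g, boom, 0)
        assert ind.fitness == 0.0
        assert "fold collapsed" in ind.note

    def test_out_of_range_fitness_rejected(self, toy_space):
        g = random_genome(toy_space, np.random.default_rng(0))
        with pytest.raises(ValueError, match="AUC"):
            evaluate_individual(g, lambda genome, seed: 1.2, 0)


class TestSelection:
    def test_elites_always_survive(self, toy_space, rng):
        pop = _individuals([0.9, 0.8, 0.7, 0.3, 0.2, 0.15, 0.12, 0.1, 0.05, 0.0],
                           toy_space, rng)
        survivors = select_survivors(pop, 0.4, 0.0, np.random.default_rng(0))
        assert [s.fitness for s in survivors] == [0.9, 0.8, 0.7, 0.3]

    def test_rejection_keeps_losers_at_expected_rate(self, toy_space, rng):
        pop = _individuals([1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
                           toy_space, rng)
        # retention 0.1 keeps exactly the single winner; count lucky losers
        kept = 0
        trials = 2000
        sel_rng = np.random.default_rng(0)
        for _ in range(trials):
            survivors = select_survivors(pop, 0.1, 0.10, sel_rng)
            kept += len(survivors) - 1
        rate = kept / (trials * 9)
        assert abs(rate - 0.10) < 0.02

    def test_reject_elites_mode_never_returns_empty(self, toy_space, rng):
        pop = _individuals([0.9, 0.8], toy_space, rng)
        survivors = select_survivors(
            pop, 1.0, 1.0, np.random.default_rng(0), reject_elites=True
        )
        assert len(survivors) == 1 and survivors[0].fitness == 0.9

    def test_deterministic_ranking_under_fitness_ties(self, toy_space, rng):
        pop = _individuals([0.5] * 6, toy_space, rng)
        a = select_survivors(pop, 0.5, 0.0, np.random.default_rng(0))
        b = select_survivors(list(reversed(pop)), 0.5, 0.0, np.random.default_rng(0))
        assert [i.genome for i in a] == [i.genome for i in b]


class TestBreeding:
    def test_child_axes_come_from_parents_without_mutation(self, toy_space):
        rng = np.random.default_rng(0)
        for _ in range(50):
            mother = random_genome(toy_space, rng)
            father = random_genome(toy_space, rng)
            child = breed(mother, father, toy_space, 0.0, rng)
            for ax in toy_space.axes:
                assert child.choices[ax.name] in (
                    mother.choices[ax.name],
                    father.choices[ax.name],
                )

    def test_mutation_changes_at_most_one_axis(self, toy_space):
        rng = np.random.default_rng(1)
        mother = random_genome(toy_space, rng)
        father = mother  # identical parents isolate the mutation
        for _ in range(200):
            child = breed(mother, father, toy_space, 1.0, rng)
            diffs = sum(
                child.choices[ax.name] != mother.choices[ax.name]
                for ax in toy_space.axes
            )
            assert diffs <= 1

    def test_mutation_rate_observed(self, toy_space):
        rng = np.random.default_rng(2)
        mother = random_genome(toy_space, rng)
        n = 4000
        mutated = 0
        for _ in range(n):
            child = breed(mother, mother, toy_space, 0.20, rng)
            if child != mother:
                mutated += 1
        # a resampled axis can land on the original label, so the observed
        # change rate is mutation_prob * E[1 - 1/len(axis)]
        axis_sizes = [len(ax) for ax in toy_space.axes]
        expected = 0.20 * np.mean([1 - 1 / s for s in axis_sizes])
        assert abs(mutated / n - expected) < 0.03


class TestEvolve:
    def test_best_fitness_is_monotone(self, toy_space):
        fit = hidden_optimum_fitness(toy_space, seed=9)
        config = GAConfig(generations=6, population_size=8, master_seed=0)
        hist = evolve(toy_space, config, lambda g, s: fit(g))
        trace = hist.best_fitness_trace()
        assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_serial_parallel_equivalence(self, toy_space):
        fit = hidden_optimum_fitness(toy_space, seed=4)
        base = dict(generations=5, population_size=10, master_seed=7)
        serial = evolve(toy_space, GAConfig(**base), lambda g, s: fit(g))
        parallel = evolve(
            toy_space,
            GAConfig(**base, max_parallel_evaluations=4),
            lambda g, s: fit(g),
        )
        for rs, rp in zip(serial.records, parallel.records):
            assert [i.genome for i in rs.individuals] == [
                i.genome for i in rp.individuals
            ]
            assert [i.fitness for i in rs.individuals] == [
                i.fitness for i in rp.individuals
            ]

    def test_cache_prevents_reevaluation(self, toy_space):
        calls = []

        def fit(genome, seed):
            calls.append(genome)
            return 0.5

        config = GAConfig(generations=8, population_size=12, master_seed=1)
        hist = evolve(toy_space, config, fit)
        assert len(calls) == len(set(calls))  # each genome evaluated once
        assert hist.evaluations == len(calls) <= cardinality(toy_space)

    def test_history_frame_shape(self, toy_space):
        fit = hidden_optimum_fitness(toy_space, seed=2)
        config = GAConfig(generations=3, population_size=6, master_seed=0)
        hist = evolve(toy_space, config, lambda g, s: fit(g))
        frame = hist.to_frame()
        assert len(frame) == 3 * 6
        assert {"generation", "rank", "fitness", "alpha", "beta", "gamma"} <= set(
            frame.columns
        )

    def test_top_k_distinct_and_warns_when_short(self, toy_space):
        fit = hidden_optimum_fitness(toy_space, seed=2)
        config = GAConfig(generations=4, population_size=6, master_seed=0)
        hist = evolve(toy_space, config, lambda g, s: fit(g))
        top = top_k(hist, 3)
        assert len(set(i.genome for i in top)) == len(top) <= 3
        with pytest.warns(UserWarning, match="distinct"):
            top_k(hist, 1000)


class TestExploredFraction:
    def test_simple_ratio(self, toy_space):
        assert explored_fraction(6, toy_space) == 6 / 12

    def test_full_scale_budget(self):
        from radopt.search_space import build_phase1_space

        space = build_phase1_space()
        assert explored_fraction(1000, space) == pytest.approx(
            1000 / 19_051_200
        )
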