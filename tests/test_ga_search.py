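"""GA operators: encoding constraints, operator algebra, calibration, evolution."""

import warnings

import numpy as np
import pytest

from evombn.ga_search import (ALLOWED_LEVELS, CachingEvaluator, GAConfig, Individual,
                              crossover, evolve, fitness, init_population,
                              is_valid_genome, mutate, mutation_step, random_genome,
                              select, validate_genome)

REFERENCE_GENOME = (2, 4, 4, 6, 6, 6, 8, 8, 10, 10, 14, 17)


class TestValidateGenome:
    def test_reference_genome_passes(self):
        assert validate_genome(REFERENCE_GENOME) == []

    def test_odd_element_rejected(self):
        violations = validate_genome((3,) + REFERENCE_GENOME[1:])
        assert any("odd" in v for v in violations)

    def test_wrong_length_rejected(self):
        assert any("length" in v for v in validate_genome(REFERENCE_GENOME[:11]))

    def test_all_violations_reported(self):
        violations = validate_genome((3, 18, 0) + REFERENCE_GENOME[3:])
        assert len(violations) >= 3


class TestInitPopulation:
    def test_size_and_validity(self):
        pop = init_population(GAConfig(seed=0))
        assert len(pop) == 100
        assert all(is_valid_genome(ind.genome) for ind in pop)

    def test_seed_determinism(self):
        a = init_population(GAConfig(seed=5))
        b = init_population(GAConfig(seed=5))
        assert [i.genome for i in a] == [i.genome for i in b]

    def test_elementwise_uniformity(self):
        """Each of the 9 allowed levels appears with frequency 1/9 +- 0.01
        over 1e5 uniform draws."""
        rng = np.random.default_rng(123)
        draws = np.array([random_genome(rng) for _ in range(100_000 // 12 + 1)])
        flat = draws.ravel()[:100_000]
        for level in ALLOWED_LEVELS:
            freq = np.mean(flat == level)
            assert abs(freq - 1 / 9) < 0.01


class TestFitness:
    def test_reference_hand_value(self):
        # genome with depth sum 131: 0.8 + 0.09 - 0.00131
        genome = (17, 12, 17, 2, 2, 16, 14, 2, 2, 14, 16, 17)
        assert sum(genome) == 131
        np.testing.assert_allclose(fitness(0.8, 0.9, genome), 0.88869, atol=1e-9)

    def test_zero_performance_floor(self):
        np.testing.assert_allclose(fitness(0.0, 0.0, (2,) * 12), -2.4e-4, atol=1e-12)

    def test_monotone_complexity_penalty(self):
        deep = fitness(0.7, 0.7, (17,) * 12)
        shallow = fitness(0.7, 0.7, (2,) * 12)
        assert shallow > deep


class TestSelect:
    def _pop(self, fitnesses):
        pop = []
        for i, f in enumerate(fitnesses):
            ind = Individual((2,) * 12)
            ind.fitness = f
            pop.append(ind)
        return pop

    def test_top_k_by_fitness(self):
        pop = self._pop(list(range(1, 101)))
        parents = select(pop, 10)
        assert sorted(p.fitness for p in parents) == list(range(91, 101))

    def test_whole_population(self):
        pop = self._pop([3.0, 1.0, 2.0])
        assert len(select(pop, 3)) == 3

    def test_tie_break_prefers_lighter_genome(self):
        a = Individual((17, 12, 17, 2, 2, 16, 14, 2, 2, 14, 16, 17))  # sum 131
        b = Individual((2,) * 12)                                     # sum 24
        a.fitness = b.fitness = 1.0
        assert select([a, b], 1)[0] is b

    def test_unevaluated_rejected(self):
        with pytest.raises(ValueError):
            select([Individual((2,) * 12)], 1)


class TestCrossover:
    def test_central_splice(self):
        child_a, child_b = crossover(REFERENCE_GENOME, (17,) * 12)
        assert child_a == (2, 4, 4, 6, 6, 6, 17, 17, 17, 17, 17, 17)
        assert child_b == (17, 17, 17, 17, 17, 17, 8, 8, 10, 10, 14, 17)

    def test_identical_parents(self):
        assert crossover(REFERENCE_GENOME, REFERENCE_GENOME) == (REFERENCE_GENOME,
                                                           REFERENCE_GENOME)

    def test_involution_recovers_parents(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a, b = random_genome(rng), random_genome(rng)
            ca, cb = crossover(a, b)
            assert set(crossover(ca, cb)) == {a, b}

    def test_children_valid(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            for child in crossover(random_genome(rng), random_genome(rng)):
                assert is_valid_genome(child)


class TestMutate:
    def test_forced_reset_to_two(self):
        rng = np.random.default_rng(0)
        out = mutate((17,) * 12, rng, k=3, p1=1.0, p2=0.0)
        assert sum(1 for v in out if v == 2) == 3

    def test_forced_reset_to_seventeen(self):
        rng = np.random.default_rng(0)
        out = mutate((2,) * 12, rng, k=4, p1=0.0, p2=1.0)
        assert sum(1 for v in out if v == 17) == 4

    def test_exactly_k_distinct_positions(self):
        rng = np.random.default_rng(1)
        base = (4,) * 12  # 4 is neither reset target, so every reset is visible
        for _ in range(50):
            out = mutate(base, rng, k=3, p1=0.8, p2=0.2)
            changed = sum(1 for a, b in zip(base, out) if a != b)
            assert changed == 3
            assert all(v in (2, 4, 17) for v in out)

    def test_output_always_valid(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            assert is_valid_genome(mutate(random_genome(rng), rng))

    def test_k_out_of_range_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            mutate((2,) * 12, rng, k=13)

    def test_reset_probability_calibration(self):
        """Over 1e4 seeded resets the fraction set to 2 is 0.8 +- 0.02."""
        rng = np.random.default_rng(42)
        base = (4,) * 12
        twos = total = 0
        for _ in range(10_000 // 3 + 1):
            out = mutate(base, rng, k=3, p1=0.8, p2=0.2)
            twos += sum(1 for v in out if v == 2)
            total += 3
        assert abs(twos / total - 0.8) < 0.02


class TestMutationStep:
    def test_application_rate(self):
        rng = np.random.default_rng(9)
        genomes = [random_genome(rng) for _ in range(10_000)]
        _, mask = mutation_step(genomes, rng, GAConfig())
        assert abs(mask.mean() - 0.25) < 0.02

    def test_unselected_genomes_unchanged(self):
        rng = np.random.default_rng(10)
        genomes = [random_genome(rng) for _ in range(200)]
        out, mask = mutation_step(genomes, rng, GAConfig())
        for g, o, hit in zip(genomes, out, mask):
            if not hit:
                assert g == o


class TestGAConfig:
    def test_defaults_match_protocol(self):
        cfg = GAConfig()
        assert (cfg.pop_size, cfg.n_parents, cfg.k) == (100, 10, 3)
        assert (cfg.p1, cfg.p2, cfg.pm) == (0.8, 0.2, 0.25)
        assert (cfg.max_generations, cfg.patience) == (10, 2)
        assert (cfg.alpha, cfg.beta, cfg.eta) == (1.0, 0.1, 1e-5)

    @pytest.mark.parametrize("kwargs", [
        dict(p1=0.9, p2=0.2), dict(pm=0.0), dict(n_parents=100),
        dict(k=0), dict(eta=-1e-5),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GAConfig(**kwargs)


class TestEvolve:
    def test_constant_fitness_stops_after_patience(self):
        """An evaluator inducing exactly constant fitness (F1 compensates the
        depth penalty) triggers the early stop immediately: 1 + patience
        generations."""
        cfg = GAConfig(pop_size=30, seed=3)
        _, history = evolve(lambda g: (0.5 + cfg.eta * sum(g), 0.0, True), cfg)
        assert len(history) == 1 + cfg.patience

    def test_plateau_semantics(self):
        """The run always ends patience generations after the final maximum
        first appears, or at the generation cap."""
        cfg = GAConfig(pop_size=30, seed=3)
        _, history = evolve(lambda g: (0.5, 0.5, True), cfg)
        maxes = [h["max_fitness"] for h in history]
        first = next(i for i, m in enumerate(maxes)
                     if abs(m - maxes[-1]) <= 1e-12)
        assert len(history) == min(cfg.max_generations, first + 1 + cfg.patience)

    def test_strictly_improving_runs_to_cap(self):
        calls = {"n": 0}

        def improving(genome):
            calls["n"] += 1
            return min(1.0, calls["n"] * 1e-4), 0.0, True

        _, history = evolve(improving, GAConfig(pop_size=30, seed=4))
        assert len(history) == 10

    def test_elitism_max_fitness_non_decreasing(self):
        rng = np.random.default_rng(0)
        for run in range(10):
            def noisy(genome, r=np.random.default_rng(run)):
                return float(r.random()), float(r.random()), True

            _, history = evolve(noisy, GAConfig(pop_size=20, n_parents=4,
                                                seed=run))
            maxes = [h["max_fitness"] for h in history]
            assert all(b >= a - 1e-12 for a, b in zip(maxes, maxes[1:]))

    def test_planted_optimum_beats_random_search(self, planted_optimum_results):
        """Evolution outperforms an equal-scale random search on landscapes
        with a planted optimum: positive mean fitness margin and a win rate
        at least the 4-in-5 level over the seeded replicates."""
        wins, margins = planted_optimum_results
        assert np.mean(margins) > 0
        assert sum(wins) >= 0.8 * len(wins)

    def test_fitness_cache_prevents_reevaluation(self):
        evaluator = CachingEvaluator(lambda g: (0.5, 0.5, True))
        evolve(evaluator, GAConfig(pop_size=30, seed=1))
        assert evaluator.cache_hits > 0
        before = evaluator.calls
        for genome in list(evaluator.cache)[:5]:
            evaluator(genome)
        assert evaluator.calls == before

    def test_failing_evaluator_floors_fitness(self):
        def flaky(genome):
            if genome[0] == 2:
                raise RuntimeError("boom")
            return 0.5, 0.5, True

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best, history = evolve(flaky, GAConfig(pop_size=30, seed=2))
        assert best.genome[0] != 2
        assert np.isfinite(best.fitness)
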