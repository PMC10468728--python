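"""Wright-Fisher simulator: operations, invariants, and both engines."""

import numpy as np
import pytest

from gammalethal.wright_fisher import (Haplotype, Individual, Mutation,
                                       SimConfig, fitness, make_gamete,
                                       mutate_gamete, next_generation,
                                       run_simulation, sample_haplotypes,
                                       sample_selection_coefficient)


def hap(*mutations):
    return Haplotype.from_mutations([Mutation(p, s) for p, s in mutations])


def individual(h1=None, h2=None, sex="female"):
    return Individual(selected=(h1 or Haplotype.empty(), h2 or Haplotype.empty()),
                      neutral=(Haplotype.empty(), Haplotype.empty()), sex=sex)


class TestSelectionCoefficients:
    def test_degenerate_mean_zero(self, rng):
        cfg = SimConfig(s_mean=0.0)
        assert sample_selection_coefficient(cfg, rng) == 0.0

    def test_mean_and_variance_match_gamma(self, rng):
        cfg = SimConfig(s_mean=1000.0, beta=0.4, ne_assumed=500.0)
        draws = sample_selection_coefficient(cfg, rng, size=1_000_000)
        # E(s) = S_mean / (2 Ne) = 1; Var(S) = S_mean^2 / beta on the S scale
        assert np.mean(draws) == pytest.approx(1.0, rel=0.01)
        S = draws * 2 * cfg.ne_assumed
        assert np.var(S) == pytest.approx(cfg.s_mean**2 / cfg.beta, rel=0.05)

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(beta=-1.0)


class TestFitness:
    def test_empty_product_is_one(self):
        assert fitness(individual()) == 1.0

    def test_single_heterozygote(self):
        assert fitness(individual(hap((0.5, 0.5)))) == pytest.approx(0.75)

    def test_homozygous_lethal(self):
        h = hap((0.5, 1.0))
        assert fitness(individual(h, h)) == 0.0

    def test_het_lethal_factor_clamps_to_inviable(self):
        # two s=3 heterozygotes would give (-0.5)^2 = 0.25 as a raw
        # product; the clamp keeps lethal carriers inviable
        h = hap((0.2, 3.0), (0.7, 3.0))
        assert fitness(individual(h)) == 0.0

    def test_matches_naive_position_set_oracle(self, rng):
        for _ in range(25):
            shared = [(p, s) for p, s in zip(rng.uniform(0, 10, 3),
                                             rng.uniform(0, 0.4, 3))]
            own1 = [(p, s) for p, s in zip(rng.uniform(0, 10, 4),
                                           rng.uniform(0, 0.4, 4))]
            own2 = [(p, s) for p, s in zip(rng.uniform(0, 10, 2),
                                           rng.uniform(0, 0.4, 2))]
            h1, h2 = hap(*shared, *own1), hap(*shared, *own2)
            pos1 = {m.position: m.s for m in h1.mutations}
            pos2 = {m.position: m.s for m in h2.mutations}
            w = 1.0
            for p, s in pos1.items():
                w *= (1 - s) if p in pos2 else (1 - s / 2)
            for p, s in pos2.items():
                if p not in pos1:
                    w *= 1 - s / 2
            assert fitness(individual(h1, h2)) == pytest.approx(w)


class TestMakeGamete:
    def test_identical_homologs_yield_identical_gamete(self, rng):
        h = hap((1.0, 0.1), (4.0, 0.2), (9.0, 0.3))
        for _ in range(10):
            g = make_gamete((h, h), 10.0, rng)
            np.testing.assert_array_equal(g.positions, h.positions)

    def test_no_crossover_returns_one_parent(self, scripted_rng_factory):
        a, b = hap((1.0, 0.1)), hap((8.0, 0.2))
        g0 = make_gamete((a, b), 10.0,
                         scripted_rng_factory(poisson=[0], uniform=[np.empty(0)],
                                              integers=[0]))
        np.testing.assert_array_equal(g0.positions, a.positions)
        g1 = make_gamete((a, b), 10.0,
                         scripted_rng_factory(poisson=[0], uniform=[np.empty(0)],
                                              integers=[1]))
        np.testing.assert_array_equal(g1.positions, b.positions)

    def test_single_crossover_joins_blocks(self, scripted_rng_factory):
        # A carries sites only in [0, 5), B only in [5, 10]; one crossover
        # at 5.0 joins A's left block to B's right block (or the complement)
        a = hap((1.0, 0.0), (4.9, 0.0))
        b = hap((5.1, 0.0), (9.0, 0.0))
        g = make_gamete((a, b), 10.0,
                        scripted_rng_factory(poisson=[1],
                                             uniform=[np.array([5.0])],
                                             integers=[0]))
        np.testing.assert_array_equal(g.positions, [1.0, 4.9, 5.1, 9.0])
        g = make_gamete((a, b), 10.0,
                        scripted_rng_factory(poisson=[1],
                                             uniform=[np.array([5.0])],
                                             integers=[1]))
        assert len(g) == 0  # B's left block and A's right block are empty

    def test_center_origin_tracks_crossovers(self, scripted_rng_factory):
        a, b = hap((1.0, 0.0)), hap((9.0, 0.0))
        _, origin = make_gamete(
            (a, b), 10.0,
            scripted_rng_factory(poisson=[1], uniform=[np.array([2.0])],
                                 integers=[0]),
            return_center_origin=True)
        assert origin == 1  # started on 0, one crossover before R/2


class TestMutateGamete:
    def test_u_zero_is_identity(self, rng):
        g = hap((3.0, 0.1))
        out = mutate_gamete(g, SimConfig(U=0.0), True, rng)
        np.testing.assert_array_equal(out.positions, g.positions)

    def test_poisson_mean_and_neutral_effects(self, rng):
        cfg = SimConfig(U=1.0, s_mean=1000.0)
        counts, all_s = [], []
        for _ in range(3000):
            out = mutate_gamete(Haplotype.empty(), cfg, False, rng)
            counts.append(len(out))
            all_s.extend(out.s)
        assert np.mean(counts) == pytest.approx(1.0, abs=0.06)
        assert np.all(np.asarray(all_s) == 0.0)  # neutral chromosome: s = 0

    def test_result_sorted_with_effects(self, rng):
        cfg = SimConfig(U=5.0, s_mean=100.0, beta=0.4)
        out = mutate_gamete(hap((5.0, 0.2)), cfg, True, rng)
        assert np.all(np.diff(out.positions) > 0)
        assert np.any(out.s > 0)


class TestNextGeneration:
    def _clean_pop(self, N):
        return [individual(sex="female" if i < N // 2 else "male")
                for i in range(N)]

    def test_mutation_free_population_stays_full_size(self, rng):
        cfg = SimConfig(N=20, U=0.0, qlocus_enabled=False)
        out = next_generation(self._clean_pop(20), cfg, rng)
        assert len(out) == 20
        assert sum(i.sex == "female" for i in out) == 10
        assert all(fitness(i) == 1.0 for i in out)

    def test_zero_fitness_parent_has_no_offspring(self, rng):
        cfg = SimConfig(N=20, U=0.0, qlocus_enabled=False)
        pop = self._clean_pop(20)
        lethal = hap((3.33, 1.0))
        pop[3] = Individual(selected=(lethal, lethal),
                            neutral=(Haplotype.empty(), Haplotype.empty()),
                            sex="female")
        for _ in range(5):
            out = next_generation(pop, cfg, rng)
            # her private marker position can only descend from her
            assert not any(3.33 in i.selected[0].positions
                           or 3.33 in i.selected[1].positions for i in out)

    def test_fitness_weighted_mating_fractions(self, rng):
        # half the mothers have w = 0.5 (one het with s = 1); the fit
        # class should contribute ~2/3 of maternal gametes, so marked
        # offspring arise at rate (1/3) * (1/2) = 1/6
        N = 40
        pop = self._clean_pop(N)
        for k in range(N // 4):
            marker = hap((0.25 + 1e-6 * k, 1.0))
            pop[k] = Individual(selected=(marker, Haplotype.empty()),
                                neutral=(Haplotype.empty(), Haplotype.empty()),
                                sex="female")
        cfg = SimConfig(N=N, U=0.0, qlocus_enabled=False)
        carried = total = 0
        for _ in range(120):
            for child in next_generation(pop, cfg, rng):
                total += 1
                carried += bool(len(child.selected[0]) or len(child.selected[1]))
        assert carried / total == pytest.approx(1 / 6, abs=0.02)

    def test_zero_total_fitness_raises(self, rng):
        from gammalethal.wright_fisher import SimulationError
        lethal = hap((1.0, 1.0))
        pop = [Individual(selected=(lethal, lethal),
                          neutral=(Haplotype.empty(), Haplotype.empty()),
                          sex="female" if i < 2 else "male")
               for i in range(4)]
        with pytest.raises(SimulationError):
            next_generation(pop, SimConfig(N=4, U=0.0), rng, generation=0)


class TestRunSimulation:
    def test_u_zero_stays_mutation_free(self):
        cfg = SimConfig(N=20, U=0.0, s_mean=500.0, burnin_generations=30,
                        seed=1)
        res = run_simulation(cfg, engine="reference")
        assert all(len(h) == 0 for i in res.population
                   for h in (*i.selected, *i.neutral))
        assert res.log["mean_fitness"].iloc[-1] == 1.0

    def test_reference_engine_reproducible_from_seed(self, tiny_cfg):
        a = run_simulation(tiny_cfg, engine="reference")
        b = run_simulation(tiny_cfg, engine="reference")
        assert a.log.equals(b.log)
        for x, y in zip(a.population, b.population):
            np.testing.assert_array_equal(x.selected[0].positions,
                                          y.selected[0].positions)
            np.testing.assert_array_equal(x.qlocus, y.qlocus)

    def test_fast_engine_reproducible_from_seed(self, tiny_cfg):
        a = run_simulation(tiny_cfg, engine="fast")
        b = run_simulation(tiny_cfg, engine="fast")
        assert a.log.equals(b.log)
        for x, y in zip(a.population, b.population):
            np.testing.assert_array_equal(x.neutral[0].positions,
                                          y.neutral[0].positions)

    def test_all_individuals_viable_under_selection(self, tiny_cfg):
        res = run_simulation(tiny_cfg, engine="fast")
        assert all(fitness(i) > 0 for i in res.population)

    @pytest.mark.parametrize("engine", ["reference", "fast"])
    def test_neutral_segregating_sites_near_watterson(self, engine):
        # theta = 4 N U per chromosome; E[S_20] = theta * H_19.  One
        # genealogy per replicate, so the tolerance is generous.
        N, U, reps = 60, 0.5, 3
        theta = 4 * N * U
        expected = theta * np.sum(1 / np.arange(1, 20))
        seg = []
        for seed in range(reps):
            cfg = SimConfig(N=N, U=U, s_mean=0.0, seed=seed,
                            qlocus_enabled=False,
                            record_every=200, purge_every=50)
            res = run_simulation(cfg, engine=engine)
            rng = np.random.default_rng(seed)
            neutral, _ = sample_haplotypes(res.population, 10, rng)
            sfs_sites = len({p for h in neutral for p in h.positions
                             if sum(p in set(g.positions) for g in neutral) < 20})
            seg.append(sfs_sites)
        assert np.mean(seg) == pytest.approx(expected, rel=0.45)


class TestSampleHaplotypes:
    def test_full_population_sample(self, rng):
        pop = [individual(sex="female" if i < 2 else "male") for i in range(4)]
        neutral, selected = sample_haplotypes(pop, 4, rng)
        assert len(neutral) == len(selected) == 8

    def test_default_sample_is_twenty_haplotypes(self, rng):
        pop = [individual(sex="female" if i < 25 else "male")
               for i in range(50)]
        neutral, selected = sample_haplotypes(pop, 10, rng)
        assert len(neutral) == len(selected) == 20

    def test_same_seed_same_sample(self):
        pop = [individual(sex="female" if i < 10 else "male")
               for i in range(20)]
        a = sample_haplotypes(pop, 5, np.random.default_rng(3))
        b = sample_haplotypes(pop, 5, np.random.default_rng(3))
        assert [id(h) for h in a[0]] == [id(h) for h in b[0]]

    def test_oversampling_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_haplotypes([individual()], 2, rng)
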