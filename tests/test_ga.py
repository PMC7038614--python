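"""Genetic-algorithm operators: counts, empirical rates, invariants."""

import math

import numpy as np
import pytest

import acidevo as ae
from acidevo.ga import (LC, UC, MutationStats, genome_mutations,
                        mutate_genome, phenotypic_mutations)
from conftest import make_context


def default_config(**overrides):
    kwargs = dict(population_size=500, generations=1, seed=0)
    kwargs.update(overrides)
    return ae.GAConfig(**kwargs)


class TestConfig:
    def test_defaults_are_consistent(self):
        cfg = default_config()
        assert cfg.population_size == 500
        assert cfg.elimination_fraction == 0.05
        assert (cfg.selection_random, cfg.selection_wildtype,
                cfg.selection_bottom) == (0.01, 0.02, 0.07)

    def test_inconsistent_selection_split_rejected(self):
        with pytest.raises(ae.ModelError):
            ae.GAConfig(selection_random=0.05)

    def test_rates_outside_unit_interval_rejected(self):
        with pytest.raises(ae.ModelError):
            ae.GAConfig(mutation_rate=1.5)


class TestInitPopulation:
    def test_default_population_is_500_wildtypes(self, toy_model):
        pop = ae.init_population(toy_model, default_config())
        assert len(pop) == 500
        lb, ub = toy_model.bounds()
        for ind in pop[:5] + pop[-5:]:
            np.testing.assert_array_equal(ind.chromosome1, lb)
            np.testing.assert_array_equal(ind.chromosome2, ub)

    def test_small_population_honoured(self, toy_model):
        cfg = default_config(population_size=4)
        assert len(ae.init_population(toy_model, cfg)) == 4


class TestEliminate:
    def test_counts_at_default_size(self):
        rng = np.random.default_rng(0)
        f = np.arange(500, dtype=float)
        out = ae.eliminate(f, default_config(), rng)
        assert len(out) == 25
        assert len(set(out.tolist())) == 25

    def test_top_half_is_safe(self):
        rng = np.random.default_rng(1)
        f = np.arange(100, dtype=float)
        cfg = default_config(population_size=100)
        for _ in range(2000):
            assert np.all(ae.eliminate(f, cfg, rng) < 50)

    def test_bottom_half_uniform_probability(self):
        """Each bottom-half individual is hit with p = 25/250 = 0.1."""
        rng = np.random.default_rng(2)
        f = np.arange(500, dtype=float)
        cfg = default_config()
        hits = np.zeros(500)
        n = 4000
        for _ in range(n):
            hits[ae.eliminate(f, cfg, rng)] += 1
        p = hits[:250] / n
        se = math.sqrt(0.1 * 0.9 / n)
        assert abs(p.mean() - 0.1) < 3 * se
        assert np.all(hits[250:] == 0)


class TestSelectParents:
    def test_counts_and_split_at_default_size(self):
        rng = np.random.default_rng(3)
        f = np.arange(500, dtype=float)
        cfg = default_config()
        victims = ae.eliminate(f, cfg, rng)
        pairs = ae.select_parents(f, victims, cfg, rng)
        assert len(pairs) == 25
        flat = [i for pair in pairs for i in pair]
        assert len(flat) == 50
        assert sum(1 for i in flat if i == -1) == 10  # fresh wild-types
        real = [i for i in flat if i >= 0]
        assert len(real) == len(set(real))  # no reuse

    def test_never_selects_eliminated(self):
        rng = np.random.default_rng(4)
        f = np.arange(500, dtype=float)
        cfg = default_config()
        for _ in range(200):
            victims = ae.eliminate(f, cfg, rng)
            flat = {i for pair in ae.select_parents(f, victims, cfg, rng)
                    for i in pair if i >= 0}
            assert not flat & set(victims.tolist())

    def test_bottom_pool_share(self):
        """35 of the 50 parents come from the fitness bottom half."""
        rng = np.random.default_rng(5)
        f = np.arange(500, dtype=float)
        cfg = default_config()
        victims = ae.eliminate(f, cfg, rng)
        counts = []
        for _ in range(300):
            flat = [i for pair in ae.select_parents(f, victims, cfg, rng)
                    for i in pair]
            counts.append(sum(1 for i in flat if 0 <= i < 250))
        # 35 bottom picks plus on average 2.5 of the 5 population-wide
        assert 35 <= np.mean(counts) <= 40


class TestRecombine:
    def _parents(self, n=200):
        a = ae.Individual(np.zeros(n), np.zeros(n))
        b = ae.Individual(np.ones(n), np.ones(n))
        return a, b

    def test_rate_zero_clones_dominant(self, ):
        rng = np.random.default_rng(6)
        a, b = self._parents()
        cfg = default_config(recombination_rate=0.0)
        c1, c2 = ae.recombine(a, b, cfg, rng)
        assert np.all(c1 == c1[0]) and np.all(c2 == c1[0])

    def test_child_genes_come_from_parents(self):
        rng = np.random.default_rng(7)
        a, b = self._parents()
        c1, c2 = ae.recombine(a, b, default_config(), rng)
        assert set(np.unique(np.concatenate([c1, c2]))) <= {0.0, 1.0}

    def test_empirical_nondominant_fraction(self):
        """Mean inheritance from the non-dominant parent is 4%."""
        rng = np.random.default_rng(8)
        a, b = self._parents(100)
        cfg = default_config()
        fracs = []
        for _ in range(10_000):
            c1, c2 = ae.recombine(a, b, cfg, rng)
            genes = np.concatenate([c1, c2])
            dominant = round(np.mean(genes))  # majority source
            fracs.append(np.mean(genes != dominant))
        mean = float(np.mean(fracs))
        se = float(np.std(fracs) / math.sqrt(len(fracs)))
        assert abs(mean - 0.04) < 3 * se

    def test_length_mismatch_rejected(self):
        rng = np.random.default_rng(9)
        a = ae.Individual(np.zeros(5), np.zeros(5))
        b = ae.Individual(np.ones(6), np.ones(6))
        with pytest.raises(ae.ModelError):
            ae.recombine(a, b, default_config(), rng)


class TestLaplaceScale:
    def test_relative_to_wildtype_flux(self, lactate_context):
        ctx = lactate_context
        j = ctx.model.reaction_index("GLYC")
        assert abs(ctx.wildtype_flux[j]) > 0
        lb, ub = ctx.model.bounds()
        b = ae.laplace_scale(ctx, j, lb, ub)
        assert b == pytest.approx(0.1 * abs(ctx.wildtype_flux[j]))

    def test_falls_back_to_max_flux_then_default(self, lactate_context):
        ctx = lactate_context
        lb, ub = ctx.model.bounds()
        # LDH carries no wild-type flux but has capacity: 0.1 * max flux
        j = ctx.model.reaction_index("LDH")
        assert ctx.wildtype_flux[j] == pytest.approx(0.0, abs=1e-9)
        b = ae.laplace_scale(ctx, j, lb, ub)
        mf = ae.max_flux(ctx.model, lb, ub, "LDH")
        assert mf > 0 and b == pytest.approx(0.1 * mf)
        assert b > 0


class TestMutateGenome:
    def test_empirical_mutation_rate(self, lactate_context):
        """Per-gene draw probability matches the configured 0.02."""
        ctx = lactate_context
        rng = np.random.default_rng(10)
        total = MutationStats()
        n_off = 3000
        for _ in range(n_off):
            c1, c2 = ctx.lb0.copy(), ctx.ub0.copy()
            total.add(mutate_genome(c1, c2, ctx, rng))
        rate = total.genes_mutated / total.genes_total
        p = ctx.config.mutation_rate
        se = math.sqrt(p * (1 - p) / total.genes_total)
        assert abs(rate - p) < 3 * se

    def test_empirical_forcing_acceptance(self, lactate_context):
        """~30% of flux-forcing proposals survive the secondary gate."""
        ctx = lactate_context
        rng = np.random.default_rng(11)
        total = MutationStats()
        while total.forcing_proposed < 3000:
            c1, c2 = ctx.lb0.copy(), ctx.ub0.copy()
            total.add(mutate_genome(c1, c2, ctx, rng))
        rate = total.forcing_kept / total.forcing_proposed
        se = math.sqrt(0.3 * 0.7 / total.forcing_proposed)
        assert abs(rate - 0.3) < 3 * se

    def test_protected_genes_never_change(self, lactate_context):
        ctx = lactate_context
        rng = np.random.default_rng(12)
        prot = ctx.protected_genes[:ctx.n]
        for _ in range(2000):
            c1, c2 = ctx.lb0.copy(), ctx.ub0.copy()
            mutate_genome(c1, c2, ctx, rng)
            np.testing.assert_array_equal(c1[prot], ctx.lb0[prot])
            np.testing.assert_array_equal(c2[prot], ctx.ub0[prot])

    def test_bound_sandwich_always_holds(self, lactate_context):
        ctx = lactate_context
        rng = np.random.default_rng(13)
        for _ in range(2000):
            c1, c2 = ctx.lb0.copy(), ctx.ub0.copy()
            mutate_genome(c1, c2, ctx, rng)
            assert np.all(ctx.lb0 - 1e-12 <= c1)
            assert np.all(c1 <= c2)
            assert np.all(c2 <= ctx.ub0 + 1e-12)

    def test_forcing_bounds_capped_at_one_percent_of_max_flux(
            self, lactate_context):
        """Kept forcing mutations force at most 1% of the reaction's
        maximum flux (wild-type bounds give the loosest reference)."""
        ctx = lactate_context
        rng = np.random.default_rng(14)
        lb0, ub0 = ctx.model.bounds()
        checked = 0
        for _ in range(4000):
            c1, c2 = ctx.lb0.copy(), ctx.ub0.copy()
            mutate_genome(c1, c2, ctx, rng)
            for (j, side, mutant, wt) in genome_mutations(
                    ctx, ae.Individual(c1, c2)):
                if side == LC and mutant > 0:
                    cap = 0.01 * ae.max_flux(ctx.model, lb0, ub0,
                                             ctx.model.reaction_ids[j],
                                             problem=ctx.problem)
                    assert mutant <= cap + 1e-9
                    checked += 1
        assert checked > 10  # the scenario actually occurred


class TestRecordingRule:
    def test_wildtype_clone_not_recorded(self, lactate_context):
        ctx = lactate_context
        assert not ae.should_record(ctx, ctx.wildtype, ctx.wildtype.F)

    def test_first_producer_recorded_in_adapted_mode(self, lactate_context):
        ctx = lactate_context
        lb, ub = ctx.lb0.copy(), ctx.ub0.copy()
        ub[ctx.model.reaction_index("ETC_NADH")] = 0.4
        ub[ctx.model.reaction_index("ETC_FADH")] = 0.0
        res = ctx.evaluate(lb, ub)
        assert res.phase2.p2 > 0
        assert ae.should_record(ctx, res, best_so_far=1e9)

    def test_citrate_rule_uses_thresholds(self, citrate_context):
        ctx = citrate_context
        better = ctx.wildtype
        import dataclasses
        improved = dataclasses.replace(better, F=better.F * 1.05)
        # beats the running max -> recorded
        assert ae.should_record(ctx, improved, best_so_far=better.F)
        # below both the max and 110% of wild-type -> not recorded
        assert not ae.should_record(ctx, improved,
                                    best_so_far=better.F * 1.2)
        jumped = dataclasses.replace(better, F=better.F * 1.15)
        assert ae.should_record(ctx, jumped, best_so_far=better.F * 1.2)

    def test_phenotype_filter_drops_slack_bounds(self, lactate_context):
        """A mutated bound the flux does not touch is not a mutation."""
        ctx = lactate_context
        lb, ub = ctx.lb0.copy(), ctx.ub0.copy()
        j_etc = ctx.model.reaction_index("ETC_NADH")
        j_icl = ctx.model.reaction_index("ICL")
        ub[j_etc] = 0.4          # binding: flux rides this bound
        ub[j_icl] = 500.0        # slack: ICL flux stays far below
        res = ctx.evaluate(lb, ub, need_fluxes=True)
        kept = {(j, side) for (j, side, *_ ) in phenotypic_mutations(
            ctx, ae.Individual(lb, ub), res.fluxes)}
        assert (j_etc, UC) in kept
        assert (j_icl, UC) not in kept


class TestRunEvolution:
    def test_population_size_constant_and_monotone_best(
            self, toy_model, phases, constants):
        cfg = ae.GAConfig(population_size=40, generations=60, seed=2,
                          target_acid="lactate", fitness_mode="adapted",
                          maxflux_cache=True)
        log = ae.run_evolution(toy_model, phases[1], constants, cfg,
                               "EX_lac_e")
        assert len(log.best_fitness) == 60
        diffs = np.diff(log.best_fitness)
        assert np.all(diffs >= -1e-12)

    def test_identical_seed_identical_log(self, toy_model, phases,
                                          constants):
        def run():
            cfg = ae.GAConfig(population_size=30, generations=40, seed=5,
                              target_acid="lactate",
                              fitness_mode="adapted", maxflux_cache=True)
            return ae.run_evolution(toy_model, phases[1], constants, cfg,
                                    "EX_lac_e")

        a, b = run(), run()
        assert a.to_json() == b.to_json()

    def test_citrate_fitness_strictly_improves(self, toy_model, phases,
                                               constants):
        """Growth-tuning mutations beat the wild-type citric producer."""
        cfg = ae.GAConfig(population_size=100, generations=200, seed=1,
                          target_acid="citrate", fitness_mode="simple",
                          maxflux_cache=True)
        log = ae.run_evolution(toy_model, phases[1], constants, cfg,
                               "EX_cit_e")
        assert log.best_fitness[-1] > log.wildtype_fitness * 1.001

    def test_wildtype_genes_persist_in_gene_pool(self, toy_model, phases,
                                                 constants):
        """Fresh wild-type parents keep original bounds in circulation."""
        cfg = ae.GAConfig(population_size=40, generations=150, seed=3,
                          target_acid="lactate", fitness_mode="adapted",
                          maxflux_cache=True)
        rng = np.random.default_rng(cfg.seed)
        ctx = ae.EvolutionContext(toy_model, phases[1], constants, cfg,
                                  "EX_lac_e")
        pop = ae.init_population(toy_model, cfg)
        for ind in pop:
            ind.fitness = ctx.wildtype
        # run a plain loop to keep access to the final population
        from acidevo.ga import recombine as rec
        for gen in range(cfg.generations):
            f = np.array([i.fitness.F for i in pop])
            victims = ae.eliminate(f, cfg, rng)
            pairs = ae.select_parents(f, victims, cfg, rng)
            children = []
            for a_, b_ in pairs:
                pa = pop[a_] if a_ >= 0 else ae.Individual(
                    ctx.lb0.copy(), ctx.ub0.copy())
                pb = pop[b_] if b_ >= 0 else ae.Individual(
                    ctx.lb0.copy(), ctx.ub0.copy())
                c1, c2 = rec(pa, pb, cfg, rng)
                mutate_genome(c1, c2, ctx, rng)
                child = ae.Individual(c1, c2)
                child.fitness = ctx.evaluate(c1, c2)
                children.append(child)
            for slot, child in zip(victims, children):
                pop[int(slot)] = child
        wt_fraction = np.mean([
            np.mean((ind.chromosome1 == ctx.lb0)
                    & (ind.chromosome2 == ctx.ub0)) for ind in pop])
        assert wt_fraction > 0.5

    def test_protected_reactions_never_mutated_in_runs(self, toy_model,
                                                       phases, constants):
        cfg = ae.GAConfig(population_size=30, generations=80, seed=4,
                          target_acid="lactate", fitness_mode="adapted",
                          maxflux_cache=True)
        log = ae.run_evolution(toy_model, phases[1], constants, cfg,
                               "EX_lac_e")
        protected = {toy_model.reaction_index(r)
                     for r in ae.detect_protected(toy_model)}
        mutated = {j for r in log.records for (j, *_ ) in r.mutations}
        assert not mutated & protected


class TestResume:
    def test_resumed_run_continues_from_final_population(
            self, toy_model, phases, constants):
        cfg = ae.GAConfig(population_size=30, generations=60, seed=8,
                          target_acid="lactate", fitness_mode="adapted",
                          maxflux_cache=True)
        first = ae.run_evolution(toy_model, phases[1], constants, cfg,
                                 "EX_lac_e")
        assert len(first.final_population) == 30
        # round-trip through JSON as the CLI does
        restored = ae.EvolutionLog.from_json(first.to_json())
        second = ae.run_evolution(toy_model, phases[1], constants, cfg,
                                  "EX_lac_e", resume_from=restored)
        assert second.best_fitness[0] >= first.best_fitness[-1] - 1e-9
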