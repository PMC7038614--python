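"""Genetic algorithm over flux-bound genomes.

Each individual carries two chromosomes aligned to the model's reaction
order: chromosome 1 holds lower bounds, chromosome 2 upper bounds, so each
reaction contributes two "genes" (an LC and a UC site). The population is
initialised as wild-type copies and cycles through fitness evaluation,
elimination (random draw from the fitness-ranked bottom half), selection
(population-wide + fresh wild-types + bottom-half), per-gene recombination
from a dominant parent, and Laplace-step mutation with three control steps
that tame flux-forcing mutations.

Mutation detail that matters: the first mutation of a still-wild-type gene
starts from the reaction's wild-type FLUX value, not from the (typically
+/-1000) default bound — that is what lets a single mutation place a
meaningful constraint. Subsequent mutations step from the current mutant
bound. Bounds never leave the original [lb, ub] interval, so irreversible
reactions can never be made reversible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .fba import FbaProblem, max_flux
from .fermentation import FitnessConstants, PhaseParameterisation
from .fitness import SIMPLE, FitnessResult, evaluate_individual
from .model import MetabolicModel, ModelError, detect_protected

LC = "LC"  # mutation on the lower bound (chromosome 1)
UC = "UC"  # mutation on the upper bound (chromosome 2)

#: tolerance for "mutant flux equals the mutant bound" (phenotype filter)
PHENOTYPE_TOL = 1e-6

#: tolerance for treating a bound as mutated relative to wild-type
GENE_TOL = 1e-12


@dataclass
class GAConfig:
    population_size: int = 500
    elimination_fraction: float = 0.05
    selection_random: float = 0.01
    selection_wildtype: float = 0.02
    selection_bottom: float = 0.07
    recombination_rate: float = 0.04
    mutation_rate: float = 0.02
    forcing_rate: float = 0.3       # acceptance of flux-forcing mutations
    forcing_cap: float = 0.01       # cap: fraction of max flux
    laplace_location: float = 0.0
    laplace_default_scale: float = 0.01
    laplace_relative_scale: float = 0.1
    generations: int = 1000
    seed: int = 0
    target_acid: str = "citrate"
    fitness_mode: str = SIMPLE
    weight: float = 10.0
    maxflux_cache: bool = False     # cap against wild-type max flux
    record_threshold: float = 1.1   # x wild-type fitness recording rule

    def __post_init__(self) -> None:
        sel = self.selection_random + self.selection_wildtype \
            + self.selection_bottom
        if not math.isclose(sel, 2 * self.elimination_fraction,
                            rel_tol=1e-9, abs_tol=1e-12):
            raise ModelError(
                "selection fractions must sum to twice the elimination "
                f"fraction ({sel} != {2 * self.elimination_fraction})")
        for name in ("elimination_fraction", "selection_random",
                     "selection_wildtype", "selection_bottom",
                     "recombination_rate", "mutation_rate", "forcing_rate",
                     "forcing_cap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ModelError(f"{name} must be in [0, 1], got {v}")


@dataclass
class Individual:
    chromosome1: np.ndarray          # lower bounds
    chromosome2: np.ndarray          # upper bounds
    fitness: FitnessResult | None = None
    lineage: int = 0                 # generation created


@dataclass
class MutationStats:
    genes_total: int = 0         # non-protected genes visited
    genes_mutated: int = 0       # genes drawn for mutation
    forcing_proposed: int = 0    # drawn mutations classified flux-forcing
    forcing_kept: int = 0        # forcing mutations surviving the gate

    def add(self, other: "MutationStats") -> None:
        self.genes_total += other.genes_total
        self.genes_mutated += other.genes_mutated
        self.forcing_proposed += other.forcing_proposed
        self.forcing_kept += other.forcing_kept


@dataclass
class RecordedIndividual:
    generation: int
    fitness: float
    mutations: list  # (reaction_index, side, mutant_bound, wildtype_bound)


@dataclass
class EvolutionLog:
    best_fitness: list[float]
    records: list[RecordedIndividual]
    config: dict
    seed: int
    wildtype_fitness: float
    mutation_stats: MutationStats = field(default_factory=MutationStats)
    #: genome diffs of the final population (enables resuming a run)
    final_population: list[list] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed,
            "config": self.config,
            "wildtype_fitness": self.wildtype_fitness,
            "best_fitness": self.best_fitness,
            "records": [{"generation": r.generation, "fitness": r.fitness,
                         "mutations": [list(m) for m in r.mutations]}
                        for r in self.records],
            "final_population": [[list(m) for m in ind]
                                 for ind in self.final_population],
        })

    @classmethod
    def from_json(cls, text: str) -> "EvolutionLog":
        d = json.loads(text)
        return cls(best_fitness=d["best_fitness"],
                   records=[RecordedIndividual(
                       generation=r["generation"], fitness=r["fitness"],
                       mutations=[tuple(m) for m in r["mutations"]])
                       for r in d["records"]],
                   config=d["config"], seed=d["seed"],
                   wildtype_fitness=d["wildtype_fitness"],
                   final_population=[[tuple(m) for m in ind]
                                     for ind in
                                     d.get("final_population", [])])


class EvolutionContext:
    """Per-run immutable state shared by the GA operators."""

    def __init__(self, model: MetabolicModel,
                 phase2: PhaseParameterisation,
                 constants: FitnessConstants,
                 config: GAConfig,
                 target_exchange_id: str):
        self.model = model
        self.phase2 = phase2
        self.constants = constants
        self.config = config
        self.target_exchange_id = target_exchange_id
        self.problem = FbaProblem(model)
        self.lb0, self.ub0 = model.bounds()
        self.n = len(model.reactions)
        protected = detect_protected(model)
        mask = np.array([r.id in protected for r in model.reactions])
        #: per-gene protection, genes 0..n-1 = chromosome 1, n..2n-1 = chr 2
        self.protected_genes = np.concatenate([mask, mask])
        wt = self.evaluate(self.lb0, self.ub0, need_fluxes=True)
        if wt.fluxes is None:
            raise ModelError("wild-type phase-2 FBA is infeasible; check "
                             "the phase parameterisation")
        self.wildtype = wt
        self.wildtype_flux = wt.fluxes
        self._maxflux_wt: dict[tuple[str, str], float] = {}

    def evaluate(self, lb, ub, need_fluxes: bool = False) -> FitnessResult:
        return evaluate_individual(
            self.model, lb, ub, self.phase2, self.constants,
            self.target_exchange_id, mode=self.config.fitness_mode,
            weight=self.config.weight, problem=self.problem,
            need_fluxes=need_fluxes)

    def max_flux(self, reaction_index: int, direction: str,
                 lb, ub) -> float:
        rid = self.model.reaction_ids[reaction_index]
        if self.config.maxflux_cache:
            key = (rid, direction)
            if key not in self._maxflux_wt:
                self._maxflux_wt[key] = max_flux(
                    self.model, self.lb0, self.ub0, rid, direction,
                    problem=self.problem)
            return self._maxflux_wt[key]
        return max_flux(self.model, lb, ub, rid, direction,
                        problem=self.problem)


# -- operators ---------------------------------------------------------------

def init_population(model: MetabolicModel, config: GAConfig
                    ) -> list[Individual]:
    """population_size wild-type copies (original bounds as genome)."""
    lb, ub = model.bounds()
    return [Individual(lb.copy(), ub.copy())
            for _ in range(config.population_size)]


def _bottom_half(fitness_values: np.ndarray) -> np.ndarray:
    """Indices of the fitness-ranked bottom 50% (stable on ties)."""
    order = np.argsort(fitness_values, kind="stable")
    return order[: len(order) // 2]


def eliminate(fitness_values, config: GAConfig,
              rng: np.random.Generator) -> np.ndarray:
    """Draw ceil(elimination_fraction * N) victims from the bottom half.

    Every bottom-half individual is equally likely; the top half is safe.
    """
    f = np.asarray(fitness_values, dtype=float)
    n_out = math.ceil(config.elimination_fraction * len(f))
    pool = _bottom_half(f)
    return rng.choice(pool, size=n_out, replace=False)


def select_parents(fitness_values, eliminated, config: GAConfig,
                   rng: np.random.Generator) -> list[tuple[int, int]]:
    """Pick 2x(eliminated count) parents and pair them.

    Three sources: selection_random*N uniformly from the whole population,
    selection_wildtype*N fresh wild-type individuals (index -1), and the
    remainder uniformly from the bottom half. Eliminated or already
    selected individuals are never picked. Pairing is a uniform shuffle
    into consecutive pairs.
    """
    f = np.asarray(fitness_values, dtype=float)
    N = len(f)
    n_parents = 2 * math.ceil(config.elimination_fraction * N)
    n_random = round(config.selection_random * N)
    n_wt = round(config.selection_wildtype * N)
    n_bottom = n_parents - n_random - n_wt
    excluded = set(int(i) for i in eliminated)

    chosen: list[int] = []
    pool_all = np.array([i for i in range(N) if i not in excluded])
    pick = rng.choice(pool_all, size=n_random, replace=False)
    chosen.extend(int(i) for i in pick)
    excluded.update(chosen)

    chosen.extend([-1] * n_wt)  # fresh wild-types

    bottom = [int(i) for i in _bottom_half(f) if i not in excluded]
    if len(bottom) < n_bottom:
        raise ModelError("bottom-half selection pool exhausted")
    pick = rng.choice(np.array(bottom), size=n_bottom, replace=False)
    chosen.extend(int(i) for i in pick)

    order = rng.permutation(len(chosen))
    shuffled = [chosen[i] for i in order]
    return [(shuffled[2 * k], shuffled[2 * k + 1])
            for k in range(len(shuffled) // 2)]


def recombine(parent_a: Individual, parent_b: Individual,
              config: GAConfig, rng: np.random.Generator
              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene inheritance from a randomly chosen dominant parent.

    Each gene (each bound entry, across both chromosomes independently) is
    taken from the non-dominant parent with probability
    ``recombination_rate``, else from the dominant parent.
    """
    if parent_a.chromosome1.shape != parent_b.chromosome1.shape:
        raise ModelError("parent genome lengths differ")
    if rng.random() < 0.5:
        dom, rec = parent_a, parent_b
    else:
        dom, rec = parent_b, parent_a
    n = len(dom.chromosome1)
    take_rec = rng.random(2 * n) < config.recombination_rate
    c1 = np.where(take_rec[:n], rec.chromosome1, dom.chromosome1)
    c2 = np.where(take_rec[n:], rec.chromosome2, dom.chromosome2)
    return c1.copy(), c2.copy()


def laplace_scale(ctx: EvolutionContext, reaction_index: int,
                  lb, ub) -> float:
    """Laplace scale b for one reaction's genes.

    Relative to |wild-type flux|; if that is zero, relative to the
    wild-type maximum flux; if both are zero, the default 0.01.
    """
    cfg = ctx.config
    wt_flux = abs(ctx.wildtype_flux[reaction_index])
    if wt_flux > GENE_TOL:
        return cfg.laplace_relative_scale * wt_flux
    mf = abs(ctx.max_flux(reaction_index, "max", lb, ub))
    if mf > GENE_TOL:
        return cfg.laplace_relative_scale * mf
    return cfg.laplace_default_scale


def mutate_genome(chromosome1: np.ndarray, chromosome2: np.ndarray,
                  ctx: EvolutionContext, rng: np.random.Generator
                  ) -> MutationStats:
    """Mutate a genome in place; returns operator statistics.

    Genes are visited in random order; each non-protected gene mutates
    with probability ``mutation_rate`` by adding a Laplace(0, b) draw.
    Control steps: (i) with the default scale the draw's sign is forced
    away from flux-forcing (negative for chromosome 1, positive for
    chromosome 2); (ii) a mutation that would force flux — make v = 0
    infeasible for its reaction — survives only with probability
    ``forcing_rate``; (iii) surviving forcing bounds are capped to
    ``forcing_cap`` of the reaction's maximum flux. Results are clipped
    into the original bounds and kept ordered (lb <= ub).
    """
    cfg = ctx.config
    n = ctx.n
    stats = MutationStats()
    genes = np.flatnonzero(~ctx.protected_genes)
    rng.shuffle(genes)
    stats.genes_total = len(genes)
    for g in genes:
        if rng.random() >= cfg.mutation_rate:
            continue
        stats.genes_mutated += 1
        j = int(g % n)
        is_lower = g < n
        chrom = chromosome1 if is_lower else chromosome2
        original = ctx.lb0[j] if is_lower else ctx.ub0[j]
        b = laplace_scale(ctx, j, chromosome1, chromosome2)
        draw = rng.laplace(cfg.laplace_location, b)
        if b == cfg.laplace_default_scale:
            draw = -abs(draw) if is_lower else abs(draw)
        # first mutation of a wild-type gene steps from the wild-type flux
        if abs(chrom[j] - original) <= GENE_TOL:
            base = ctx.wildtype_flux[j]
        else:
            base = chrom[j]
        value = base + draw
        # clip into the original interval: bounds never widen
        value = min(max(value, ctx.lb0[j]), ctx.ub0[j])
        forcing = (is_lower and value > 0.0) or \
                  (not is_lower and value < 0.0)
        if forcing:
            stats.forcing_proposed += 1
            if rng.random() >= cfg.forcing_rate:
                continue  # forcing mutation suppressed
            stats.forcing_kept += 1
            if is_lower:
                cap = cfg.forcing_cap * max(
                    0.0, ctx.max_flux(j, "max", chromosome1, chromosome2))
                value = min(value, cap)
                if value <= 0.0:
                    continue  # no forward capacity: suppress
            else:
                cap = cfg.forcing_cap * max(
                    0.0, -ctx.max_flux(j, "min", chromosome1, chromosome2))
                value = max(value, -cap)
                if value >= 0.0:
                    continue
        chrom[j] = value
        # keep lb <= ub: the mutated bound wins, the other is clipped to it
        if is_lower and chromosome2[j] < value:
            chromosome2[j] = value
        elif not is_lower and chromosome1[j] > value:
            chromosome1[j] = value
    return stats


def genome_mutations(ctx: EvolutionContext, ind: Individual) -> list:
    """Genome diff vs wild-type: (reaction_index, side, mutant, wildtype)."""
    out = []
    d1 = np.flatnonzero(np.abs(ind.chromosome1 - ctx.lb0) > GENE_TOL)
    d2 = np.flatnonzero(np.abs(ind.chromosome2 - ctx.ub0) > GENE_TOL)
    for j in d1:
        out.append((int(j), LC, float(ind.chromosome1[j]),
                    float(ctx.lb0[j])))
    for j in d2:
        out.append((int(j), UC, float(ind.chromosome2[j]),
                    float(ctx.ub0[j])))
    return out


def phenotypic_mutations(ctx: EvolutionContext, ind: Individual,
                         fluxes: np.ndarray) -> list:
    """Keep only mutations whose reaction flux sits on the mutant bound.

    A bound that the flux does not touch has no phenotypic effect and is
    filtered from the record.
    """
    kept = []
    for (j, side, mutant, wt) in genome_mutations(ctx, ind):
        if abs(fluxes[j] - mutant) <= PHENOTYPE_TOL:
            kept.append((j, side, mutant, wt))
    return kept


def should_record(ctx: EvolutionContext, fitness: FitnessResult,
                  best_so_far: float) -> bool:
    """Recording rule for the evolution output.

    If the wild type does not produce the target acid, any individual that
    does is recorded. Otherwise an individual is recorded when its fitness
    beats the running maximum or exceeds ``record_threshold`` (110%) of
    the wild-type fitness.
    """
    wt_produces = ctx.wildtype.phase2.p2 > PHENOTYPE_TOL
    if not wt_produces:
        return fitness.phase2.p2 > PHENOTYPE_TOL
    return (fitness.F > best_so_far or
            fitness.F > ctx.config.record_threshold * ctx.wildtype.F)


def run_evolution(model: MetabolicModel,
                  phase2: PhaseParameterisation,
                  constants: FitnessConstants,
                  config: GAConfig,
                  target_exchange_id: str,
                  progress: bool = False,
                  resume_from: EvolutionLog | None = None) -> EvolutionLog:
    """Run the full GA loop for ``config.generations`` generations.

    Only newly created individuals are evaluated; survivors keep their
    cached fitness. Deterministic for a fixed seed. With ``resume_from``
    the initial population is rebuilt from the stored final population
    of an earlier log (genomes re-evaluated once) instead of wild-types.
    """
    rng = np.random.default_rng(config.seed)
    ctx = EvolutionContext(model, phase2, constants, config,
                           target_exchange_id)
    if resume_from is not None and resume_from.final_population:
        population = []
        for diffs in resume_from.final_population:
            lb, ub = ctx.lb0.copy(), ctx.ub0.copy()
            for (j, side, mutant, _wt) in diffs:
                (lb if side == LC else ub)[int(j)] = float(mutant)
            ind = Individual(lb, np.maximum(lb, ub))
            ind.fitness = ctx.evaluate(ind.chromosome1, ind.chromosome2)
            population.append(ind)
        if len(population) != config.population_size:
            raise ModelError(
                f"resume log population {len(population)} does not match "
                f"configured size {config.population_size}")
    else:
        population = init_population(model, config)
        for ind in population:
            ind.fitness = ctx.wildtype
    best = max(ind.fitness.F for ind in population)
    log = EvolutionLog(best_fitness=[], records=[], config=asdict(config),
                       seed=config.seed, wildtype_fitness=ctx.wildtype.F)

    for gen in range(config.generations):
        f = np.array([ind.fitness.F for ind in population])
        victims = eliminate(f, config, rng)
        pairs = select_parents(f, victims, config, rng)
        children = []
        for a, b in pairs:
            pa = population[a] if a >= 0 else Individual(
                ctx.lb0.copy(), ctx.ub0.copy())
            pb = population[b] if b >= 0 else Individual(
                ctx.lb0.copy(), ctx.ub0.copy())
            c1, c2 = recombine(pa, pb, config, rng)
            stats = mutate_genome(c1, c2, ctx, rng)
            log.mutation_stats.add(stats)
            child = Individual(c1, c2, lineage=gen + 1)
            child.fitness = ctx.evaluate(c1, c2)
            if should_record(ctx, child.fitness, best):
                full = ctx.evaluate(c1, c2, need_fluxes=True)
                muts = phenotypic_mutations(ctx, child, full.fluxes) \
                    if full.fluxes is not None else []
                log.records.append(RecordedIndividual(
                    generation=gen + 1, fitness=child.fitness.F,
                    mutations=muts))
            children.append(child)
        for slot, child in zip(victims, children):
            population[int(slot)] = child
        best = max(best, max(c.fitness.F for c in children)) \
            if children else best
        log.best_fitness.append(best)
        if progress and (gen + 1) % 200 == 0:
            print(f"  generation {gen + 1}: best fitness {best:.4f}")
    log.final_population = [genome_mutations(ctx, ind)
                            for ind in population]
    return log
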