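"""Post-processing of evolution logs into engineering-target tables.

Recorded individuals are reduced to *solutions*: the near-optimal records
(fitness above 95% of the best) are pruned by complementation — each
mutation is reverted to wild-type in turn while keeping the others, and
retained only if the fitness drops by more than 5% — leaving the mutation
sets that actually carry the phenotype. Mutation frequencies across
solutions then point at the reproducible targets, and a representative
solution (near-maximal fitness, composed of high-frequency mutations) is
picked for downstream dynamic modelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ga import LC, UC, EvolutionContext, EvolutionLog
from .model import ModelError

#: solutions must exceed this fraction of the best recorded fitness
SOLUTION_THRESHOLD = 0.95

#: complementation fitness-decrease (fraction) above which a mutation stays
PRUNE_THRESHOLD = 0.05


@dataclass
class MutationRecord:
    reaction_index: int
    side: str                 # LC or UC
    mutant_bound: float
    wildtype_bound: float

    def __post_init__(self) -> None:
        if self.side not in (LC, UC):
            raise ModelError(f"mutation side must be LC or UC, got "
                             f"{self.side!r}")


@dataclass
class ComplementationMetrics:
    fitness_decrease_pct: float
    acid_flux_decrease_pct: float
    growth_increase_pct: float


@dataclass
class Solution:
    mutations: list[MutationRecord]
    fitness: float
    generation: int = 0
    complementation: list[ComplementationMetrics] = field(
        default_factory=list)


class SolutionEvaluator:
    """Re-evaluates mutation sets against the run's model and constants."""

    def __init__(self, ctx: EvolutionContext):
        self.ctx = ctx

    def genome(self, mutations: list[MutationRecord]
               ) -> tuple[np.ndarray, np.ndarray]:
        lb = self.ctx.lb0.copy()
        ub = self.ctx.ub0.copy()
        for m in mutations:
            if m.side == LC:
                lb[m.reaction_index] = m.mutant_bound
            else:
                ub[m.reaction_index] = m.mutant_bound
        return lb, np.maximum(lb, ub)

    def evaluate(self, mutations: list[MutationRecord]):
        lb, ub = self.genome(mutations)
        return self.ctx.evaluate(lb, ub)


def _as_records(mutations) -> list[MutationRecord]:
    out = []
    for m in mutations:
        if isinstance(m, MutationRecord):
            out.append(m)
        else:
            j, side, mutant, wt = m
            out.append(MutationRecord(int(j), side, float(mutant),
                                      float(wt)))
    return out


def extract_solutions(log: EvolutionLog) -> list[Solution]:
    """Solution candidates: records with fitness > 95% of the maximum."""
    if not log.records:
        raise ModelError("evolution log contains no recorded individuals")
    fmax = max(r.fitness for r in log.records)
    return [Solution(mutations=_as_records(r.mutations), fitness=r.fitness,
                     generation=r.generation)
            for r in log.records
            if r.fitness > SOLUTION_THRESHOLD * fmax]


def _pct_decrease(intact: float, other: float) -> float:
    if intact <= 0.0:
        return 0.0
    return 100.0 * (intact - other) / intact


def complement_mutation(solution: Solution, mutation_index: int,
                        evaluator: SolutionEvaluator
                        ) -> ComplementationMetrics:
    """Revert one mutation to wild-type, keeping the others.

    Reports the percent fitness decrease, percent target-acid flux
    decrease and percent growth (mu2) increase relative to the intact
    solution. An infeasible complemented genome counts as fitness 0.
    """
    intact = evaluator.evaluate(solution.mutations)
    rest = [m for k, m in enumerate(solution.mutations)
            if k != mutation_index]
    comp = evaluator.evaluate(rest)
    f_comp = 0.0 if comp.status == "infeasible" else comp.F
    growth_inc = 0.0
    if intact.phase2.mu2 > 0.0:
        growth_inc = 100.0 * (comp.phase2.mu2 - intact.phase2.mu2) \
            / intact.phase2.mu2
    return ComplementationMetrics(
        fitness_decrease_pct=_pct_decrease(intact.F, f_comp),
        acid_flux_decrease_pct=_pct_decrease(intact.phase2.p2,
                                             comp.phase2.p2),
        growth_increase_pct=growth_inc,
    )


def prune_solution(solution: Solution,
                   evaluator: SolutionEvaluator) -> Solution:
    """Discard mutations whose complementation costs <= 5% fitness.

    Mutations are visited in ascending (reaction_index, side) order; each
    complementation is judged against the current, already-pruned solution
    and discarded mutations are permanently reverted to wild-type. The
    surviving mutations get their complementation metrics attached.
    """
    current = sorted(solution.mutations,
                     key=lambda m: (m.reaction_index, m.side))
    k = 0
    while k < len(current):
        work = Solution(mutations=current, fitness=solution.fitness)
        metrics = complement_mutation(work, k, evaluator)
        if metrics.fitness_decrease_pct > 100.0 * PRUNE_THRESHOLD:
            k += 1
        else:
            current = current[:k] + current[k + 1:]
    result = evaluator.evaluate(current)
    pruned = Solution(mutations=current, fitness=result.F,
                      generation=solution.generation)
    pruned.complementation = [
        complement_mutation(pruned, k, evaluator)
        for k in range(len(current))]
    return pruned


@dataclass
class FrequencyTable:
    frequencies: dict[int, float]   # reaction index -> frequency
    cutoff: float
    n_solutions: int

    def filtered(self) -> dict[int, float]:
        return {j: f for j, f in self.frequencies.items()
                if f >= self.cutoff}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"reaction_index": j, "frequency": f,
                 "above_cutoff": f >= self.cutoff}
                for j, f in sorted(self.frequencies.items())]
        return pd.DataFrame(rows,
                            columns=["reaction_index", "frequency",
                                     "above_cutoff"])


def mutation_frequencies(solutions: list[Solution],
                         cutoff: float = 0.2) -> FrequencyTable:
    """Occurrence of each mutated reaction index across solutions.

    A reaction counts once per solution (an LC and a UC on the same
    reaction are one occurrence); frequency = occurrences / n solutions.
    The cutoff only affects the plot export; the raw table keeps all.
    """
    if not solutions:
        raise ModelError("no solutions to compute frequencies from")
    counts: dict[int, int] = {}
    for s in solutions:
        for j in {m.reaction_index for m in s.mutations}:
            counts[j] = counts.get(j, 0) + 1
    n = len(solutions)
    return FrequencyTable(
        frequencies={j: c / n for j, c in sorted(counts.items())},
        cutoff=cutoff, n_solutions=n)


def representative_solution(solutions: list[Solution]) -> Solution:
    """The near-optimal solution that best represents the average.

    Among solutions with fitness > 95% of the maximum, picks the one whose
    mutations have the largest summed cross-solution frequency; ties break
    to fewer mutations, then higher fitness.
    """
    if not solutions:
        raise ModelError("no solutions given")
    freqs = mutation_frequencies(solutions).frequencies
    fmax = max(s.fitness for s in solutions)
    pool = [s for s in solutions if s.fitness > SOLUTION_THRESHOLD * fmax]
    if not pool:  # the maximum itself is always in the >95% set
        pool = [s for s in solutions if s.fitness == fmax]

    def score(s: Solution):
        overlap = sum(freqs.get(j, 0.0)
                      for j in {m.reaction_index for m in s.mutations})
        return (overlap, -len(s.mutations), s.fitness)

    return max(pool, key=score)


def complementation_table(solution: Solution,
                          evaluator: SolutionEvaluator) -> pd.DataFrame:
    """Per-mutation complementation summary (Table-style CSV export)."""
    model = evaluator.ctx.model
    if len(solution.complementation) != len(solution.mutations):
        solution = replace(
            solution,
            complementation=[complement_mutation(solution, k, evaluator)
                             for k in range(len(solution.mutations))])
    rows = []
    for m, c in zip(solution.mutations, solution.complementation):
        rows.append({
            "reaction_index": m.reaction_index,
            "reaction_id": model.reaction_ids[m.reaction_index],
            "mutation_effect": m.side,
            "mutant_bound": m.mutant_bound,
            "wildtype_bound": m.wildtype_bound,
            "fitness_decrease_pct": round(c.fitness_decrease_pct, 1),
            "acid_flux_decrease_pct": round(c.acid_flux_decrease_pct, 1),
            "growth_increase_pct": round(c.growth_increase_pct, 1),
        })
    return pd.DataFrame(rows)
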