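"""Closed-form productivity fitness over phase-2 FBA fluxes.

Fitness approximates the volumetric productivity c(t_f)/t_f of a full
dynamic batch simulation using a single static FBA snapshot of the
proton-production phase plus three constants precomputed from a wild-type
dFBA run: the phase-switch time t_c, the biomass A_c and the substrate S_c
at the switch. With specific rates constant over phase 2,

    c(t_f) = p2 * S_c / f2                     (target-acid yield)
    h(t_f) = h  * S_c / f2                     (proton yield)
    t_f    = t_c + (1/mu2) ln(1 + S_c mu2 / (f2 A_c))      (mu2 > 0)
           = t_c + S_c / (f2 A_c)                          (mu2 = 0)

and the simple fitness is F = c(t_f)/t_f. For target acids the wild type
does not produce, the simple fitness is identically zero and provides no
selection gradient, so an adapted form adds the proton yield with a 10x
weight on the target acid: F = (h(t_f) + 10 c(t_f)) / t_f.

Mutant bounds are applied to phase 2 only (mutations activate at t_c);
phase 1 stays wild-type, which is what makes t_c, A_c, S_c constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fba import FbaProblem
from .fermentation import (FitnessConstants, PhaseParameterisation,
                           configure_phase, phase_objectives)
from .model import MetabolicModel

#: growth rates below this are treated as zero in the t_f branch
MU_TOL = 1e-10

SIMPLE = "simple"
ADAPTED = "adapted"


@dataclass
class PhaseFluxes:
    """Specific rates read from the phase FBA snapshots (Table-style).

    Magnitude conventions: uptakes (f1, f2, q) are reported positive.
    """

    mu2: float = 0.0   # phase-2 specific growth rate, h^-1
    f2: float = 0.0    # phase-2 substrate uptake
    p2: float = 0.0    # target-acid output flux
    h: float = 0.0     # proton output flux
    mu1: float = 0.0   # phase-1 rates (informational)
    f1: float = 0.0
    q: float = 0.0


@dataclass
class FitnessResult:
    F: float
    t_f: float
    c_tf: float
    h_tf: float
    phase2: PhaseFluxes = field(default_factory=PhaseFluxes)
    status: str = "ok"               # ok | infeasible | no_substrate_uptake
    fluxes: np.ndarray | None = None  # full phase-2 vector when requested

    def to_dict(self) -> dict:
        """JSON-serialisable summary (flux vector omitted)."""
        return {"F": self.F, "t_f": self.t_f, "c_tf": self.c_tf,
                "h_tf": self.h_tf, "status": self.status,
                "phase2": {"mu2": self.phase2.mu2, "f2": self.phase2.f2,
                           "p2": self.phase2.p2, "h": self.phase2.h}}


def estimate_yield(p2: float, f2: float, S_c: float) -> float:
    """Target-acid yield c(t_f) = p2 S_c / f2 (mmol per litre of broth)."""
    if f2 <= 0.0:
        return 0.0
    return p2 * S_c / f2


def estimate_proton_yield(h: float, f2: float, S_c: float) -> float:
    """Proton yield h(t_f) = h S_c / f2."""
    if f2 <= 0.0:
        return 0.0
    return h * S_c / f2


def estimate_tf(t_c: float, S_c: float, mu2: float, f2: float,
                A_c: float) -> float:
    """Time of substrate depletion.

    Integrates S' = -f2 A, A' = mu2 A from the phase switch; growth during
    phase 2 shortens fermentation. Returns +inf when no substrate is
    consumed (f2 = 0).
    """
    if f2 <= 0.0 or A_c <= 0.0:
        return math.inf
    if mu2 > MU_TOL:
        arg = max(1.0, 1.0 + S_c * mu2 / (f2 * A_c))
        return t_c + math.log(arg) / mu2
    return t_c + S_c / (f2 * A_c)


def fitness_simple(c_tf: float, t_f: float) -> float:
    """F = c(t_f)/t_f: mean volumetric productivity of the target acid."""
    if not math.isfinite(t_f) or t_f <= 0.0:
        return 0.0
    return c_tf / t_f


def fitness_adapted(h_tf: float, c_tf: float, t_f: float,
                    weight: float = 10.0) -> float:
    """F = (h(t_f) + weight * c(t_f)) / t_f.

    The proton term gives a nonzero gradient before the target acid ever
    appears; the weight keeps the pressure pointed at the target.
    """
    if not math.isfinite(t_f) or t_f <= 0.0:
        return 0.0
    return (h_tf + weight * c_tf) / t_f


def evaluate_individual(model: MetabolicModel,
                        chromosome1: np.ndarray,
                        chromosome2: np.ndarray,
                        phase2: PhaseParameterisation,
                        constants: FitnessConstants,
                        target_exchange_id: str,
                        mode: str = SIMPLE,
                        weight: float = 10.0,
                        problem: FbaProblem | None = None,
                        need_fluxes: bool = False) -> FitnessResult:
    """Fitness of one individual from a single phase-2 FBA.

    The individual's bound chromosomes are intersected with the phase-2
    parameterisation (phase-fixed exchanges stay authoritative — those
    reactions are not mutable anyway) and the phase is solved
    lexicographically. An infeasible LP maps to fitness 0, never an
    exception: forcing mutations can and do produce infeasible genomes.
    """
    if mode not in (SIMPLE, ADAPTED):
        raise ValueError(f"unknown fitness mode {mode!r}")
    problem = problem or FbaProblem(model)
    j_target = model.reaction_index(target_exchange_id)
    lb, ub, _ = configure_phase(model, phase2)
    ilb = np.maximum(lb, chromosome1)
    iub = np.minimum(ub, chromosome2)
    for rid in phase2.bounds:
        j = model.reaction_index(rid)
        ilb[j], iub[j] = lb[j], ub[j]
    if phase2.ngam_id:
        j = model.reaction_index(phase2.ngam_id)
        ilb[j], iub[j] = lb[j], ub[j]
    iub = np.maximum(ilb, iub)

    objs = phase_objectives(model, phase2)
    sol = problem.solve_lexicographic(ilb, iub, objs,
                                      tie_break=need_fluxes)
    if not sol.optimal:
        return FitnessResult(F=0.0, t_f=math.inf, c_tf=0.0, h_tf=0.0,
                             status="infeasible")
    v = sol.fluxes
    j_growth = model.reaction_index(phase2.growth_id)
    j_sub = model.reaction_index(phase2.substrate_id)
    j_h = model.reaction_index(phase2.objective_id)
    fluxes = PhaseFluxes(mu2=max(0.0, v[j_growth]),
                         f2=max(0.0, -v[j_sub]),
                         p2=max(0.0, v[j_target]),
                         h=max(0.0, v[j_h]))
    c_tf = estimate_yield(fluxes.p2, fluxes.f2, constants.S_c)
    h_tf = estimate_proton_yield(fluxes.h, fluxes.f2, constants.S_c)
    t_f = estimate_tf(constants.t_c, constants.S_c, fluxes.mu2, fluxes.f2,
                      constants.A_c)
    if mode == SIMPLE:
        F = fitness_simple(c_tf, t_f)
    else:
        F = fitness_adapted(h_tf, c_tf, t_f, weight)
    status = "ok" if fluxes.f2 > 0.0 else "no_substrate_uptake"
    return FitnessResult(F=F, t_f=t_f, c_tf=c_tf, h_tf=h_tf, phase2=fluxes,
                         status=status,
                         fluxes=v if need_fluxes else None)
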