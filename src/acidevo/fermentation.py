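"""Two-phase dynamic batch fermentation (dFBA).

Batch growth proceeds in two phases. In phase 1 (phosphate storage)
external phosphate is available, the FBA objective is growth, and most of
the phosphate taken up is stored as polyphosphate. When external phosphate
depletes (time ``t_c``) the culture switches to phase 2 (proton
production): external phosphate uptake stops, growth is limited by the
slow release of stored phosphate, and the FBA objective becomes proton
export — organic acids are secreted as the dissociation products that
carry those protons at low pH.

Integration is explicit Euler with the exchange fluxes held constant over
each step; the phase switch and substrate depletion are located exactly
within a step (rates are constant across a step, so the crossing time is
the linear solution — equivalent to bisecting the step to convergence).
The fitness constants ``t_c`` (switch time), ``A_c`` (biomass at switch)
and ``S_c`` (substrate at switch) are read off the simulated trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fba import FbaProblem
from .model import MetabolicModel, ModelError

PHASE_STORAGE = "phosphate_storage"
PHASE_PROTON = "proton_production"

#: successive acid-dissociation constants (pKa) of the supported acids
ACID_PKAS = {
    "citrate": (3.13, 4.76, 6.40),
    "succinate": (4.21, 5.64),
    "lactate": (3.86,),
    "malate": (3.40, 5.20),
    "acetate": (4.76,),
    "gluconate": (3.86,),
}


def dissociation_fraction(pKa: float, pH: float) -> float:
    """Dissociated fraction of one acid group: 1 / (1 + 10^(pKa - pH))."""
    return 1.0 / (1.0 + 10.0 ** (pKa - pH))


def protons_released(acid: str, pH: float) -> float:
    """Protons released per molecule of acid at the given pH.

    Sums the Henderson–Hasselbalch dissociated fraction over the acid's
    successive dissociation steps.
    """
    try:
        pkas = ACID_PKAS[acid]
    except KeyError:
        raise ModelError(f"unknown acid {acid!r}; supported: "
                         f"{sorted(ACID_PKAS)}") from None
    return float(sum(dissociation_fraction(p, pH) for p in pkas))


@dataclass
class PhaseParameterisation:
    """Fixed exchange constraints and objective for one growth phase."""

    phase: str                      # PHASE_STORAGE or PHASE_PROTON
    objective_id: str               # phase-1: growth; phase-2: proton export
    growth_id: str                  # biomass reaction id
    substrate_id: str               # substrate exchange id (uptake < 0)
    phosphate_ext_id: str           # external phosphate exchange id
    phosphate_store_id: str         # polyphosphate storage/release boundary
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    ngam_id: str = ""               # maintenance ATP reaction
    ngam: float = 1.9               # mmol gDW^-1 h^-1
    pH: float = 2.0

    def __post_init__(self) -> None:
        if self.phase not in (PHASE_STORAGE, PHASE_PROTON):
            raise ModelError(f"unknown phase {self.phase!r}")


def configure_phase(model: MetabolicModel, params: PhaseParameterisation
                    ) -> tuple[np.ndarray, np.ndarray, str]:
    """Phase-specific bound vectors and objective id for a model.

    Starts from the model's bounds, overlays the phase's fixed exchange
    constraints and applies the non-growth-associated maintenance (NGAM)
    flux as a lower bound. Unknown reaction ids raise :class:`ModelError`.
    """
    lb, ub = model.bounds()
    for rid in (params.objective_id, params.growth_id, params.substrate_id,
                params.phosphate_ext_id, params.phosphate_store_id):
        model.reaction_index(rid)  # raises on unknown ids
    for rid, (lo, hi) in params.bounds.items():
        j = model.reaction_index(rid)
        lb[j], ub[j] = lo, hi
    if params.ngam_id:
        j = model.reaction_index(params.ngam_id)
        lb[j] = max(lb[j], params.ngam)
        ub[j] = max(ub[j], lb[j])
    if params.phase == PHASE_PROTON:
        j = model.reaction_index(params.phosphate_ext_id)
        if not (lb[j] == 0.0 and ub[j] >= 0.0):
            raise ModelError("proton-production phase must forbid external "
                             "phosphate uptake (lower bound 0)")
    return lb, ub, params.objective_id


def phase_objectives(model: MetabolicModel, params: PhaseParameterisation
                     ) -> list[int]:
    """Lexicographic objective stack for a phase.

    Phase 1 maximises growth. Phase 2 maximises growth first — growth is
    phosphate-limited by the stored-phosphate release cap — then maximises
    proton export at that growth rate; acid output is read from this
    second stage.
    """
    if params.phase == PHASE_STORAGE:
        return [model.reaction_index(params.objective_id)]
    return [model.reaction_index(params.growth_id),
            model.reaction_index(params.objective_id)]


@dataclass
class BatchConditions:
    """Initial broth composition and integrator settings."""

    A0: float = 0.1        # biomass, g/L
    S0: float = 300.0      # substrate, mmol/L
    P0: float = 4.0        # external phosphate, mmol/L
    dt: float = 0.01       # h
    t_max: float = 400.0   # h
    s_tol: float = 1e-9    # substrate considered depleted below this


@dataclass
class FitnessConstants:
    t_c: float   # h, phase-switch time
    A_c: float   # g/L, biomass at switch
    S_c: float   # mmol/L, substrate at switch


@dataclass
class FermentationTrajectory:
    t: np.ndarray
    A: np.ndarray
    S: np.ndarray
    P: np.ndarray
    stored_P: np.ndarray          # mmol/L broth, polyphosphate pool
    protons: np.ndarray           # mmol/L exported
    co2: np.ndarray               # mmol/L exported (net)
    acids: dict[str, np.ndarray]  # mmol/L per acid
    phase: np.ndarray             # 1 or 2 per sample
    t_c: float | None
    t_f: float | None
    status: str                   # substrate_depleted | t_max | infeasible
    pH0: float = 2.0

    @property
    def pH(self) -> np.ndarray:
        """Broth pH from the initial proton concentration plus exports."""
        h0 = 1000.0 * 10.0 ** (-self.pH0)  # mmol/L
        return -np.log10(np.maximum(h0 + self.protons, 1e-12) / 1000.0)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"t": self.t, "biomass": self.A, "substrate": self.S,
                "phosphate": self.P, "stored_phosphate": self.stored_P,
                "protons": self.protons, "co2": self.co2,
                "phase": self.phase, "pH": self.pH}
        for acid, series in self.acids.items():
            data[acid] = series
        return pd.DataFrame(data)

    def to_plot_json(self, molar_mass: dict[str, float] | None = None,
                     substrate_mass: float | None = None) -> dict:
        """Plot-ready panels (biomass / phosphate / acids / substrate).

        Concentrations are converted to g/L where a molar mass (g/mmol)
        is known; otherwise they stay in mmol/L with a units tag.
        """
        def series(values, mass):
            if mass is None:
                return {"units": "mmol/L", "values": list(values)}
            return {"units": "g/L", "values": [v * mass for v in values]}

        molar_mass = molar_mass or {}
        return {
            "t": list(self.t),
            "t_c": self.t_c,
            "t_f": self.t_f,
            "biomass": {"units": "g/L", "values": list(self.A)},
            "phosphate": {"units": "mmol/L", "values": list(self.P)},
            "substrate": series(self.S, substrate_mass),
            "acids": {acid: series(conc, molar_mass.get(acid))
                      for acid, conc in self.acids.items()},
        }


def extract_constants(traj: FermentationTrajectory) -> FitnessConstants:
    """Fitness constants (t_c, A_c, S_c) from a wild-type trajectory."""
    if traj.t_c is None:
        raise ModelError("trajectory never reached the proton-production "
                         "phase; cannot extract fitness constants")
    i = int(np.searchsorted(traj.t, traj.t_c))
    i = min(i, len(traj.t) - 1)
    return FitnessConstants(t_c=float(traj.t_c), A_c=float(traj.A[i]),
                            S_c=float(traj.S[i]))


def _acid_exchange_ids(model: MetabolicModel) -> dict[str, str]:
    """Map acid names to their exchange reaction ids (EX_<tag>_e)."""
    from .toy import ACID_TAGS  # local import to avoid a cycle
    out = {}
    rids = set(model.reaction_ids)
    for acid, tag in ACID_TAGS.items():
        rid = f"EX_{tag}_e"
        if rid in rids:
            out[acid] = rid
    return out


def simulate_batch(model: MetabolicModel,
                   phase1: PhaseParameterisation,
                   phase2: PhaseParameterisation,
                   batch: BatchConditions,
                   individual: tuple[np.ndarray, np.ndarray] | None = None,
                   activation: str = "wild_type_in_phase1",
                   proton_exchange_id: str = "EX_h_e",
                   co2_exchange_id: str = "EX_co2_e",
                   problem: FbaProblem | None = None
                   ) -> FermentationTrajectory:
    """Euler dFBA of a batch fermentation.

    ``individual`` is an optional (chromosome1, chromosome2) bound pair;
    with the default activation rule it is applied only from the phase
    switch onward (mutations are switched off during phosphate storage).
    Mid-run infeasibility terminates the trajectory with a status flag.
    """
    if activation not in ("wild_type_in_phase1", "always"):
        raise ModelError(f"unknown activation rule {activation!r}")
    problem = problem or FbaProblem(model)
    acid_ids = _acid_exchange_ids(model)
    j_sub = {p.phase: model.reaction_index(p.substrate_id)
             for p in (phase1, phase2)}
    j_pi = model.reaction_index(phase1.phosphate_ext_id)
    j_store = model.reaction_index(phase1.phosphate_store_id)
    j_growth = model.reaction_index(phase1.growth_id)
    j_h = model.reaction_index(proton_exchange_id) \
        if proton_exchange_id in model.reaction_ids else None
    j_co2 = model.reaction_index(co2_exchange_id) \
        if co2_exchange_id in model.reaction_ids else None
    j_acids = {a: model.reaction_index(r) for a, r in acid_ids.items()}

    def phase_bounds(params):
        lb, ub, _ = configure_phase(model, params)
        use_ind = individual is not None and (
            activation == "always" or params.phase == PHASE_PROTON)
        if use_ind:
            ilb = np.maximum(lb, individual[0])
            iub = np.minimum(ub, individual[1])
            # phase-fixed exchanges stay authoritative
            for rid in params.bounds:
                j = model.reaction_index(rid)
                ilb[j], iub[j] = lb[j], ub[j]
            if params.ngam_id:
                j = model.reaction_index(params.ngam_id)
                ilb[j], iub[j] = lb[j], ub[j]
            lb, ub = ilb, np.maximum(ilb, iub)
        return lb, ub

    rows = {k: [] for k in ("t", "A", "S", "P", "stored", "h", "co2",
                            "phase")}
    cum_acids: dict[str, list] = {a: [] for a in j_acids}

    t, A, S, P = 0.0, batch.A0, batch.S0, batch.P0
    stored = 0.0
    protons = co2 = 0.0
    phase = 1
    params = phase1
    lb0, ub0 = phase_bounds(phase1)
    objs = phase_objectives(model, phase1)
    t_c = t_f = None
    status = "t_max"
    cache_key = None
    cache_flux = None
    acid_totals = {a: 0.0 for a in j_acids}

    def finish(status_):
        arr = {k: np.asarray(v, dtype=float) for k, v in rows.items()
               if k != "phase"}
        acids = {a: np.asarray(v, dtype=float)
                 for a, v in cum_acids.items()}
        return FermentationTrajectory(
            t=arr["t"], A=arr["A"], S=arr["S"], P=arr["P"],
            stored_P=arr["stored"], protons=arr["h"], co2=arr["co2"],
            acids=acids, phase=np.asarray(rows["phase"], dtype=int),
            t_c=t_c, t_f=t_f, status=status_, pH0=params.pH)

    def snapshot():
        rows["t"].append(t)
        rows["A"].append(A)
        rows["S"].append(S)
        rows["P"].append(P)
        rows["stored"].append(stored)
        rows["h"].append(protons)
        rows["co2"].append(co2)
        rows["phase"].append(phase)
        for a in j_acids:
            cum_acids[a].append(acid_totals[a])

    snapshot()

    while t < batch.t_max:
        if S <= batch.s_tol:
            t_f = t
            status = "substrate_depleted"
            break
        lb = lb0
        ub = ub0
        js = j_sub[params.phase]
        key = lb.tobytes()
        if key == cache_key:
            flux = cache_flux
        else:
            sol = problem.solve_lexicographic(lb, ub, objs, tie_break=True)
            if not sol.optimal:
                t_f = t
                status = "infeasible"
                break
            flux = sol.fluxes
            cache_key, cache_flux = key, flux

        # rates are constant across a step, so depletion times within the
        # step are exact (the limit of bisecting the step)
        dt = batch.dt
        if phase == 1 and flux[j_pi] < 0:
            t_empty = P / (-flux[j_pi] * A)
            if t_empty <= dt:
                dt = t_empty
        v_s = flux[js]
        if v_s < 0:
            t_dry = S / (-v_s * A)
            if t_dry < dt:
                dt = t_dry

        S = max(0.0, S + v_s * A * dt)
        P = max(0.0, P + flux[j_pi] * A * dt)
        stored = max(0.0, stored + flux[j_store] * A * dt)
        protons += (flux[j_h] if j_h is not None else 0.0) * A * dt
        co2 += (flux[j_co2] if j_co2 is not None else 0.0) * A * dt
        for a, j in j_acids.items():
            acid_totals[a] += flux[j] * A * dt
        A = A + flux[j_growth] * A * dt
        t += dt
        snapshot()

        if phase == 1 and P <= 0.0:
            t_c = t
            phase = 2
            params = phase2
            lb0, ub0 = phase_bounds(phase2)
            objs = phase_objectives(model, phase2)
            cache_key = cache_flux = None
    return finish(status)
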