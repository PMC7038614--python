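"""Flux-balance linear programming on persistent GLPK problems.

The genetic algorithm solves tens of thousands of small LPs per run, so the
stoichiometric matrix is loaded into a GLPK problem object once per model
and only column bounds/objective change between solves; warm-started
simplex re-solves then take microseconds.

Degenerate optima are resolved by a parsimonious secondary criterion:
at the fixed optimal objective value, total absolute flux is minimised,
which selects a unique, reproducible flux vector (needed by the
mutation-recording phenotype filter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import swiglpk as glp

from .model import MetabolicModel

#: feasibility / bound tolerance used when comparing fluxes to bounds
TOL = 1e-9

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

_STATUS = {
    glp.GLP_OPT: OPTIMAL,
    glp.GLP_FEAS: OPTIMAL,
    glp.GLP_INFEAS: INFEASIBLE,
    glp.GLP_NOFEAS: INFEASIBLE,
    glp.GLP_UNBND: UNBOUNDED,
}


@dataclass
class FluxSolution:
    status: str
    objective_value: float
    fluxes: np.ndarray | None  # aligned to model reaction order

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL


def _set_col(prob, j: int, lo: float, hi: float) -> None:
    lo_inf = np.isneginf(lo)
    hi_inf = np.isposinf(hi)
    if lo_inf and hi_inf:
        glp.glp_set_col_bnds(prob, j, glp.GLP_FR, 0.0, 0.0)
    elif lo_inf:
        glp.glp_set_col_bnds(prob, j, glp.GLP_UP, 0.0, hi)
    elif hi_inf:
        glp.glp_set_col_bnds(prob, j, glp.GLP_LO, lo, 0.0)
    elif lo == hi:
        glp.glp_set_col_bnds(prob, j, glp.GLP_FX, lo, hi)
    else:
        glp.glp_set_col_bnds(prob, j, glp.GLP_DB, lo, hi)


class FbaProblem:
    """Persistent LP formulation of S.v = 0, lb <= v <= ub for one model."""

    def __init__(self, model: MetabolicModel):
        self.model = model
        self.n = len(model.reactions)
        self.m = len(model.metabolites)
        self._prob = self._build(split=False)
        self._pfba = None  # built lazily: variables split into v+ / v-
        self._parm = glp.glp_smcp()
        glp.glp_init_smcp(self._parm)
        self._parm.msg_lev = glp.GLP_MSG_OFF
        self._parm.tol_bnd = 1e-9
        self._parm.tol_dj = 1e-9

    def _build(self, split: bool):
        S = self.model.stoichiometric_matrix().tocoo()
        prob = glp.glp_create_prob()
        glp.glp_add_rows(prob, self.m)
        for i in range(1, self.m + 1):
            glp.glp_set_row_bnds(prob, i, glp.GLP_FX, 0.0, 0.0)
        ncols = 2 * self.n if split else self.n
        glp.glp_add_cols(prob, ncols)
        nnz = S.nnz * (2 if split else 1)
        ia = glp.intArray(nnz + 1)
        ja = glp.intArray(nnz + 1)
        ar = glp.doubleArray(nnz + 1)
        k = 1
        for i, j, v in zip(S.row, S.col, S.data):
            ia[k] = int(i) + 1
            ja[k] = int(j) + 1
            ar[k] = float(v)
            k += 1
        if split:
            for i, j, v in zip(S.row, S.col, S.data):
                ia[k] = int(i) + 1
                ja[k] = int(j) + 1 + self.n
                ar[k] = -float(v)
                k += 1
        glp.glp_load_matrix(prob, nnz, ia, ja, ar)
        return prob

    # -- plain FBA ----------------------------------------------------------
    def solve(self, lb: np.ndarray, ub: np.ndarray,
              objective, sense: str = "max",
              tie_break: bool = True,
              fixed: dict[int, float] | None = None) -> FluxSolution:
        """Optimise ``objective`` over the flux polytope.

        ``objective`` is a reaction index or a ``{index: coefficient}``
        map. ``fixed`` pins additional reactions to given flux values (used
        for lexicographic solves). With ``tie_break`` the returned flux
        vector additionally minimises total absolute flux at the achieved
        objective value.
        """
        if np.any(lb > ub + TOL):
            bad = int(np.argmax(lb - ub))
            raise ValueError(f"inconsistent bounds for reaction "
                             f"{self.model.reaction_ids[bad]!r}")
        prob = self._prob
        obj = {objective: 1.0} if np.isscalar(objective) else dict(objective)
        lo = lb.copy()
        hi = ub.copy()
        if fixed:
            for j, v in fixed.items():
                lo[j] = hi[j] = v
        for j in range(self.n):
            _set_col(prob, j + 1, lo[j], hi[j])
            glp.glp_set_obj_coef(prob, j + 1, 0.0)
        for j, c in obj.items():
            glp.glp_set_obj_coef(prob, int(j) + 1, float(c))
        glp.glp_set_obj_dir(prob, glp.GLP_MAX if sense == "max"
                            else glp.GLP_MIN)
        ret = glp.glp_simplex(prob, self._parm)
        status = _STATUS.get(glp.glp_get_status(prob), INFEASIBLE)
        if ret != 0 or status != OPTIMAL:
            # warm-started bases can go stale after large bound changes;
            # one retry from a fresh standard basis settles the verdict
            glp.glp_std_basis(prob)
            glp.glp_simplex(prob, self._parm)
            status = _STATUS.get(glp.glp_get_status(prob), INFEASIBLE)
        if status != OPTIMAL:
            return FluxSolution(status, 0.0, None)
        value = glp.glp_get_obj_val(prob)
        if not tie_break:
            flux = np.array([glp.glp_get_col_prim(prob, j + 1)
                             for j in range(self.n)])
            return FluxSolution(OPTIMAL, value, flux)
        flux = self._min_total_flux(lo, hi, obj, value)
        if flux is None:  # tolerance corner: fall back to the vertex found
            flux = np.array([glp.glp_get_col_prim(prob, j + 1)
                             for j in range(self.n)])
        return FluxSolution(OPTIMAL, value, flux)

    # -- parsimonious tie-break ---------------------------------------------
    def _min_total_flux(self, lb, ub, obj: dict, value: float):
        """min sum |v| subject to S.v=0, bounds, and obj.v = value."""
        if self._pfba is None:
            self._pfba = self._build(split=True)
            # extra row fixing the primary objective value
            glp.glp_add_rows(self._pfba, 1)
        prob = self._pfba
        n = self.n
        for j in range(n):
            _set_col(prob, j + 1, max(lb[j], 0.0), max(ub[j], 0.0))
            _set_col(prob, n + j + 1, max(-ub[j], 0.0), max(-lb[j], 0.0))
            glp.glp_set_obj_coef(prob, j + 1, 1.0)
            glp.glp_set_obj_coef(prob, n + j + 1, 1.0)
        row = self.m + 1
        ind = glp.intArray(2 * len(obj) + 1)
        val = glp.doubleArray(2 * len(obj) + 1)
        k = 1
        for j, c in obj.items():
            ind[k] = int(j) + 1
            val[k] = float(c)
            k += 1
            ind[k] = int(j) + 1 + n
            val[k] = -float(c)
            k += 1
        glp.glp_set_mat_row(prob, row, k - 1, ind, val)
        eps = max(1e-9, 1e-9 * abs(value))
        glp.glp_set_row_bnds(prob, row, glp.GLP_DB, value - eps, value + eps)
        glp.glp_set_obj_dir(prob, glp.GLP_MIN)
        ret = glp.glp_simplex(prob, self._parm)
        if ret != 0 or glp.glp_get_status(prob) != glp.GLP_OPT:
            glp.glp_std_basis(prob)
            glp.glp_simplex(prob, self._parm)
        if glp.glp_get_status(prob) != glp.GLP_OPT:
            return None
        vp = np.array([glp.glp_get_col_prim(prob, j + 1) for j in range(n)])
        vn = np.array([glp.glp_get_col_prim(prob, n + j + 1)
                       for j in range(n)])
        return vp - vn

    # -- lexicographic multi-objective --------------------------------------
    def solve_lexicographic(self, lb, ub, objectives: list[int],
                            tie_break: bool = True) -> FluxSolution:
        """Maximise each objective reaction in turn, fixing earlier ones.

        Returns the flux vector of the final stage; its ``objective_value``
        is the final stage's optimum.
        """
        fixed: dict[int, float] = {}
        sol = FluxSolution(INFEASIBLE, 0.0, None)
        for stage, j in enumerate(objectives):
            last = stage == len(objectives) - 1
            sol = self.solve(lb, ub, j, "max",
                             tie_break=tie_break and last, fixed=fixed)
            if not sol.optimal:
                return sol
            fixed[j] = sol.objective_value
        return sol


def solve_fba(model: MetabolicModel, lb, ub, objective_id: str | None = None,
              sense: str = "max", tie_break: bool = True,
              problem: FbaProblem | None = None) -> FluxSolution:
    """One-shot FBA by reaction id (thin wrapper over :class:`FbaProblem`)."""
    problem = problem or FbaProblem(model)
    rid = objective_id or model.objective_id
    return problem.solve(np.asarray(lb, dtype=float),
                         np.asarray(ub, dtype=float),
                         model.reaction_index(rid), sense,
                         tie_break=tie_break)


def max_flux(model: MetabolicModel, lb, ub, reaction_id: str,
             direction: str = "max",
             problem: FbaProblem | None = None) -> float:
    """Maximum attainable flux of one reaction under the given bounds.

    The queried reaction's own (possibly mutated) bounds are relaxed to the
    model's original bounds, so the cap reflects what the rest of the
    network permits. An infeasible polytope yields 0 with a warning.
    """
    problem = problem or FbaProblem(model)
    j = model.reaction_index(reaction_id)
    lo = np.array(lb, dtype=float)
    hi = np.array(ub, dtype=float)
    rxn = model.reactions[j]
    lo[j] = rxn.lower_bound
    hi[j] = rxn.upper_bound
    sol = problem.solve(lo, hi, j, direction, tie_break=False)
    if not sol.optimal:
        warnings.warn(f"max_flux({reaction_id!r}): polytope {sol.status}; "
                      "returning 0", stacklevel=2)
        return 0.0
    return sol.objective_value


def write_fluxes(model: MetabolicModel, fluxes, path) -> None:
    """Export a flux vector as a reaction_id,flux CSV."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["reaction_id", "flux"])
        for rid, v in zip(model.reaction_ids, fluxes):
            w.writerow([rid, repr(float(v))])


def apply_individual(model: MetabolicModel, chromosome1, chromosome2
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Clip an individual's bound chromosomes into the model's bounds.

    Evolution may never widen bounds beyond the wild-type range, so the
    genome is clipped into [original lb, original ub] elementwise.
    """
    olb, oub = model.bounds()
    c1 = np.asarray(chromosome1, dtype=float)
    c2 = np.asarray(chromosome2, dtype=float)
    if c1.shape != olb.shape or c2.shape != oub.shape:
        raise ValueError(
            f"genome length {c1.shape}/{c2.shape} does not match reaction "
            f"count {olb.shape}")
    lb = np.clip(c1, olb, oub)
    ub = np.clip(c2, olb, oub)
    return lb, np.maximum(lb, ub)
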