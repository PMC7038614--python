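"""Core metabolic-model containers and model-level utilities.

The model representation is deliberately lightweight: a stoichiometric
matrix over named reactions and metabolites, per-reaction flux bounds, a
boolean gene association string and a functional category. Categories drive
which reactions the genetic algorithm may mutate (biomass, maintenance ATP,
transport, exchange and acid-dissociation reactions are immutable).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

#: reaction categories understood by the rest of the package
CATEGORIES = ("internal", "exchange", "transport", "biomass", "maintenance",
              "dissociation")

#: categories whose flux bounds are protected from mutation
PROTECTED_CATEGORIES = ("exchange", "transport", "biomass", "maintenance",
                        "dissociation")

#: molar masses (g/mmol) for broth-concentration reporting of common species
MOLAR_MASS = {
    "glucose": 0.18016,
    "citrate": 0.19212,
    "succinate": 0.11809,
    "lactate": 0.09008,
    "malate": 0.13409,
    "acetate": 0.06005,
    "gluconate": 0.19616,
}

DEFAULT_BOUND = 1000.0


class ModelError(ValueError):
    """Raised for malformed models or inconsistent bound data."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    molar_mass: float | None = None  # g/mmol
    carbon: int = 0  # carbon atoms, used by the toy balance audit


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    gene_association: str = ""
    category: str = "internal"

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} "
                f"exceeds upper bound {self.upper_bound}")
        if self.category not in CATEGORIES:
            raise ModelError(f"reaction {self.id!r}: unknown category "
                             f"{self.category!r}")


@dataclass
class ModelStats:
    n_reactions: int
    n_unique_metabolites: int
    n_unique_genes: int


@dataclass
class MetabolicModel:
    """Stoichiometry, bounds, objective and gene associations."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_id: str = ""
    _S: sparse.csr_matrix | None = field(default=None, repr=False,
                                         compare=False)

    def __post_init__(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ModelError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelError("duplicate reaction ids")
        known = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ModelError(
                    f"reaction {r.id!r} references unknown metabolites "
                    f"{sorted(missing)}")
        if self.objective_id and self.objective_id not in set(rxn_ids):
            raise ModelError(f"objective {self.objective_id!r} is not a "
                             "reaction in the model")

    # -- indexing -----------------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise ModelError(f"unknown reaction id {rid!r}") from None

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self.reaction_index(rid)]

    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolites[self.metabolite_ids.index(mid)]

    # -- numeric views ------------------------------------------------------
    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """m x n sparse stoichiometric matrix (metabolites x reactions)."""
        if self._S is None:
            midx = {m: i for i, m in enumerate(self.metabolite_ids)}
            rows, cols, vals = [], [], []
            for j, r in enumerate(self.reactions):
                for mid, coef in r.stoichiometry.items():
                    rows.append(midx[mid])
                    cols.append(j)
                    vals.append(coef)
            self._S = sparse.csr_matrix(
                (vals, (rows, cols)),
                shape=(len(self.metabolites), len(self.reactions)))
        return self._S

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    @property
    def gene_ids(self) -> set[str]:
        genes: set[str] = set()
        for r in self.reactions:
            genes |= gene_set(r.gene_association)
        return genes


_GENE_SPLIT = re.compile(r"\(|\)|\band\b|\bor\b|\bAND\b|\bOR\b")


def gene_set(association: str) -> set[str]:
    """Gene ids appearing in a boolean gene-association expression."""
    if not association:
        return set()
    return {tok for tok in (t.strip() for t in _GENE_SPLIT.split(association))
            if tok}


def model_stats(model: MetabolicModel,
                compartment_regex: str = r"[_-]?[a-z]$") -> ModelStats:
    """Reaction / unique-metabolite / unique-gene counts.

    Metabolites are counted once across compartments: a trailing
    single-letter compartment tag matching ``compartment_regex`` is stripped
    from each id before counting, so ``CIT`` and ``CIT-e`` (or ``cit_c`` and
    ``cit_e``) collapse to one species.
    """
    pat = re.compile(compartment_regex)
    bases = {pat.sub("", m.id) for m in model.metabolites}
    return ModelStats(
        n_reactions=len(model.reactions),
        n_unique_metabolites=len(bases),
        n_unique_genes=len(model.gene_ids),
    )


def detect_protected(model: MetabolicModel) -> set[str]:
    """Reaction ids whose bounds the evolution must never mutate.

    Biomass, the maintenance ATP reaction, transporters, exchanges and the
    acid-dissociation pseudo-reactions are immutable: evolution operates on
    the internal metabolic network only.
    """
    return {r.id for r in model.reactions
            if r.category in PROTECTED_CATEGORIES}


# -- tabular bound overrides ------------------------------------------------

def write_bounds_table(model: MetabolicModel, path,
                       lb: np.ndarray | None = None,
                       ub: np.ndarray | None = None) -> None:
    """Write a reaction_id,lower_bound,upper_bound CSV."""
    mlb, mub = model.bounds()
    lb = mlb if lb is None else np.asarray(lb, dtype=float)
    ub = mub if ub is None else np.asarray(ub, dtype=float)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["reaction_id", "lower_bound", "upper_bound"])
        for rid, lo, hi in zip(model.reaction_ids, lb, ub):
            w.writerow([rid, repr(float(lo)), repr(float(hi))])


def read_bounds_table(model: MetabolicModel, path
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Apply CSV bound overrides on top of the model's bounds.

    Rows may cover any subset of reactions; unlisted reactions keep their
    model bounds. Unknown reaction ids and lb > ub rows are rejected.
    """
    lb, ub = model.bounds()
    idx = {rid: i for i, rid in enumerate(model.reaction_ids)}
    unknown = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rid = row["reaction_id"]
            if rid not in idx:
                unknown.append(rid)
                continue
            lo = float(row["lower_bound"])
            hi = float(row["upper_bound"])
            if lo > hi:
                raise ModelError(
                    f"bounds table row {rid!r}: lower bound {lo} exceeds "
                    f"upper bound {hi}")
            lb[idx[rid]] = lo
            ub[idx[rid]] = hi
    if unknown:
        raise ModelError(f"bounds table names unknown reactions: {unknown}")
    return lb, ub
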