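"""SBML import/export built on cobrapy/libsbml.

Reads SBML Level 3 (FBC bounds) as well as the legacy kinetic-law bound
dialect that cobrapy understands, converts to the package's lightweight
:class:`~acidevo.model.MetabolicModel`, and infers reaction categories from
network structure plus configurable id/name patterns (SBML itself has no
category field). A JSON-serialisable load report records which dialect was
read, the category census and any bound defaults that were applied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict

from .model import (DEFAULT_BOUND, MetabolicModel, Metabolite, ModelError,
                    Reaction)


@dataclass
class CategoryRules:
    """Regex heuristics mapping reaction ids/names onto categories.

    Exchange reactions are recognised structurally (exactly one metabolite);
    the remaining special categories have no SBML encoding and are matched
    by id or name, case-insensitively.
    """

    biomass: str = r"biomass|growth"
    maintenance: str = r"atpm|maintenance|ngam"
    dissociation: str = r"diss"
    transport: str = r"transport|(?:^|_)t(?:$|\d+$)"

    def classify(self, rid: str, name: str, n_species: int) -> str:
        hay = f"{rid} {name}".lower()
        if re.search(self.biomass, hay):
            return "biomass"
        if re.search(self.maintenance, hay):
            return "maintenance"
        if re.search(self.dissociation, hay):
            return "dissociation"
        if n_species == 1:
            return "exchange"
        if re.search(self.transport, hay):
            return "transport"
        return "internal"


@dataclass
class LoadReport:
    path: str = ""
    dialect: str = "fbc"
    n_reactions: int = 0
    n_metabolites: int = 0
    category_counts: dict = field(default_factory=dict)
    defaulted_bounds: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def read_sbml(path, rules: CategoryRules | None = None
              ) -> tuple[MetabolicModel, LoadReport]:
    """Read an SBML file into a :class:`MetabolicModel`.

    Raises :class:`ModelError` naming the offending element on parse failure
    or on a reaction whose lower bound exceeds its upper bound. Reactions
    without bound information default to +/-1000, recorded in the report.
    """
    import cobra.io

    rules = rules or CategoryRules()
    report = LoadReport(path=str(path))
    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises several io error types
        raise ModelError(f"SBML parse failure for {path}: {exc}") from exc

    with open(path, "rb") as fh:
        head = fh.read(4096).decode("utf-8", "replace")
    report.dialect = "fbc" if "fbc" in head else "kinetic-law-bounds"

    mets = [Metabolite(id=m.id, name=m.name or "",
                       compartment=m.compartment or "c")
            for m in cm.metabolites]
    objective_id = ""
    rxns = []
    for r in cm.reactions:
        lb, ub = r.lower_bound, r.upper_bound
        if lb is None or ub is None:
            report.defaulted_bounds.append(r.id)
            lb = -DEFAULT_BOUND if lb is None else lb
            ub = DEFAULT_BOUND if ub is None else ub
        if lb > ub:
            raise ModelError(
                f"SBML reaction {r.id!r}: lower bound {lb} exceeds upper "
                f"bound {ub}")
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        cat = rules.classify(r.id, r.name or "", len(stoich))
        rxns.append(Reaction(id=r.id, stoichiometry=stoich,
                             lower_bound=float(lb), upper_bound=float(ub),
                             name=r.name or "",
                             gene_association=r.gene_reaction_rule or "",
                             category=cat))
        if r.objective_coefficient:
            objective_id = r.id

    model = MetabolicModel(metabolites=mets, reactions=rxns,
                           objective_id=objective_id)
    report.n_reactions = len(rxns)
    report.n_metabolites = len(mets)
    census: dict[str, int] = {}
    for r in rxns:
        census[r.category] = census.get(r.category, 0) + 1
    report.category_counts = census
    return model, report


def write_sbml(model: MetabolicModel, path) -> None:
    """Write the model as SBML Level 3 + FBC via cobrapy.

    Output is deterministic for a given model, so identical toy configs
    produce byte-identical files.
    """
    import cobra
    import cobra.io

    cm = cobra.Model("acidevo_model")
    cmets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(m.id, name=m.name,
                                compartment=m.compartment or "c")
        cmets[m.id] = cmet
    cm.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name,
                            lower_bound=r.lower_bound,
                            upper_bound=r.upper_bound)
        crxns.append(cr)
    cm.add_reactions(crxns)
    for r, cr in zip(model.reactions, crxns):
        cr.add_metabolites({cmets[mid]: c
                            for mid, c in r.stoichiometry.items()})
        if r.gene_association:
            cr.gene_reaction_rule = r.gene_association
    if model.objective_id:
        cm.objective = cm.reactions.get_by_id(model.objective_id)
    cobra.io.write_sbml_model(cm, str(path))
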