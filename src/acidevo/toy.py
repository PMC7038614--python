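"""Deterministic toy core-carbon network for organic-acid fermentation.

The generator emulates, at ~40 reactions, the structure that matters for
evolving acid output in a filamentous fungus: glucose uptake, lumped
glycolysis, the pyruvate node (lactate dehydrogenase, a pyruvate
decarboxylase route to acetate, pyruvate carboxylase), the TCA cycle with
the glyoxylate shunt and an NADH-consuming fumarate reductase, an electron
transport chain that recycles NADH/FADH2 against oxygen, a maintenance ATP
reaction, a biomass reaction with a phosphate requirement, and per-acid
dissociation reactions that emit protons according to Henderson–
Hasselbalch dissociation at the broth pH. All internal reactions are
carbon-balanced; the same config always yields an identical model.

Phosphate drives the two-phase batch behaviour: in phase 1 most phosphate
uptake is routed to a polyphosphate store, in phase 2 external uptake is
closed and a small fixed release of stored phosphate caps growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fermentation import (ACID_PKAS, BatchConditions, PHASE_PROTON,
                           PHASE_STORAGE, PhaseParameterisation,
                           protons_released)
from .model import MOLAR_MASS, MetabolicModel, Metabolite, ModelError, Reaction

#: short metabolite tags per acid (internal species and EX_<tag>_e ids)
ACID_TAGS = {
    "citrate": "cit",
    "succinate": "suc",
    "lactate": "lac",
    "malate": "mal",
    "acetate": "act",
    "gluconate": "glcnt",
}

#: internal metabolite id per acid
_ACID_MET = {
    "citrate": "CIT",
    "succinate": "SUC",
    "lactate": "LAC",
    "malate": "MAL",
    "acetate": "ACT",
    "gluconate": "GLCNT",
}

_CARBON = {
    "GLC_e": 6, "GLC": 6, "PYR": 3, "ACAL": 2, "ACCOA": 2, "OAA": 4,
    "CIT": 6, "AKG": 5, "SUC": 4, "FUM": 4, "MAL": 4, "GLX": 2, "AA": 3,
    "LAC": 3, "ACT": 2, "GLCNT": 6, "CO2": 1,
    "CIT_e": 6, "SUC_e": 4, "LAC_e": 3, "MAL_e": 4, "ACT_e": 2,
    "GLCNT_e": 6,
}

BIG = 1000.0


@dataclass
class ToyConfig:
    """Parameters of the generated network and its phase parameterisation.

    Flux values are mmol gDW^-1 h^-1 unless noted. The defaults are the
    study conditions used throughout the test-suite and acceptance runs.
    """

    acids: tuple[str, ...] = ("citrate", "succinate", "lactate", "malate",
                              "acetate", "gluconate")
    pH: float = 2.0
    phosphate_per_biomass: float = 0.05   # mmol P per gDW
    ngam: float = 1.9                     # maintenance ATP
    glucose_uptake_phase1: float = 2.0
    glucose_uptake_phase2: float = 1.4
    phosphate_uptake: float = 0.25        # phase-1 external P uptake cap
    phosphate_storage_flux: float = 0.2   # phase-1 fixed storage flux
    phosphate_release_flux: float = 0.0025  # phase-2 fixed release cap
    batch: BatchConditions = field(default_factory=BatchConditions)


def build_toy_model(config: ToyConfig | None = None) -> MetabolicModel:
    """Generate the toy model (deterministic, no RNG)."""
    cfg = config or ToyConfig()
    for acid in cfg.acids:
        if acid not in ACID_TAGS:
            raise ModelError(f"unknown acid {acid!r}; supported: "
                             f"{sorted(ACID_TAGS)}")

    mets = [
        Metabolite("GLC_e", "glucose (ext)", "e",
                   molar_mass=MOLAR_MASS["glucose"]),
        Metabolite("GLC", "glucose", "c", molar_mass=MOLAR_MASS["glucose"]),
        Metabolite("PI_e", "phosphate (ext)", "e"),
        Metabolite("PI", "phosphate", "c"),
        Metabolite("O2_e", "oxygen (ext)", "e"),
        Metabolite("O2", "oxygen", "c"),
        Metabolite("PYR", "pyruvate", "c"),
        Metabolite("ACAL", "acetaldehyde", "c"),
        Metabolite("ACCOA", "acetyl unit", "c"),
        Metabolite("OAA", "oxaloacetate", "c"),
        Metabolite("CIT", "citrate", "c", molar_mass=MOLAR_MASS["citrate"]),
        Metabolite("AKG", "2-oxoglutarate", "c"),
        Metabolite("SUC", "succinate", "c",
                   molar_mass=MOLAR_MASS["succinate"]),
        Metabolite("FUM", "fumarate", "c"),
        Metabolite("MAL", "malate", "c", molar_mass=MOLAR_MASS["malate"]),
        Metabolite("GLX", "glyoxylate", "c"),
        Metabolite("AA", "amino-acid pool", "c"),
        Metabolite("LAC", "lactate", "c", molar_mass=MOLAR_MASS["lactate"]),
        Metabolite("ACT", "acetate", "c", molar_mass=MOLAR_MASS["acetate"]),
        Metabolite("GLCNT", "gluconate", "c",
                   molar_mass=MOLAR_MASS["gluconate"]),
        Metabolite("NAD", "NAD+", "c"),
        Metabolite("NADH", "NADH", "c"),
        Metabolite("FAD", "FAD", "c"),
        Metabolite("FADH2", "FADH2", "c"),
        Metabolite("ATP", "ATP", "c"),
        Metabolite("ADP", "ADP", "c"),
        Metabolite("CO2", "CO2", "c"),
        Metabolite("H_e", "proton (ext)", "e"),
    ]
    for acid in cfg.acids:
        tag = _ACID_MET[acid]
        mets.append(Metabolite(f"{tag}_e", f"{acid} (ext)", "e",
                               molar_mass=MOLAR_MASS[acid]))
    for m in mets:
        m.carbon = _CARBON.get(m.id, 0)

    pc = cfg.phosphate_per_biomass

    def rxn(rid, stoich, lb=0.0, ub=BIG, cat="internal", gene="", name=""):
        return Reaction(rid, stoich, lower_bound=lb, upper_bound=ub,
                        category=cat, gene_association=gene, name=name)

    rxns = [
        # exchanges
        rxn("EX_glc_e", {"GLC_e": -1}, lb=-cfg.glucose_uptake_phase1,
            cat="exchange", name="glucose exchange"),
        rxn("EX_pi_e", {"PI_e": -1}, lb=-cfg.phosphate_uptake,
            cat="exchange", name="phosphate exchange"),
        rxn("EX_o2_e", {"O2_e": -1}, lb=-BIG, cat="exchange",
            name="oxygen exchange"),
        rxn("EX_co2_e", {"CO2": -1}, lb=-BIG, cat="exchange",
            name="CO2 exchange"),
        rxn("EX_h_e", {"H_e": -1}, cat="exchange", name="proton exchange"),
        # transporters
        rxn("GLCt", {"GLC_e": -1, "GLC": 1}, cat="transport",
            name="glucose transport"),
        rxn("PIt", {"PI_e": -1, "PI": 1}, cat="transport",
            name="phosphate transport"),
        rxn("O2t", {"O2_e": -1, "O2": 1}, cat="transport",
            name="oxygen transport"),
        # polyphosphate store (boundary pool, phase-controlled)
        rxn("PISTORE", {"PI": -1}, lb=-BIG, cat="exchange",
            name="polyphosphate storage/release"),
        # central carbon metabolism
        rxn("GLYC", {"GLC": -1, "NAD": -2, "ADP": -2, "PYR": 2, "NADH": 2,
                     "ATP": 2}, gene="g_glyc", name="glycolysis (lumped)"),
        rxn("GLCD", {"GLC": -1, "NAD": -1, "GLCNT": 1, "NADH": 1},
            gene="g_glcd", name="glucose dehydrogenase"),
        rxn("LDH", {"PYR": -1, "NADH": -1, "LAC": 1, "NAD": 1},
            gene="g_ldh", name="lactate dehydrogenase"),
        rxn("PDC", {"PYR": -1, "ACAL": 1, "CO2": 1}, gene="g_pdc",
            name="pyruvate decarboxylase"),
        rxn("ALDH", {"ACAL": -1, "NAD": -1, "ACT": 1, "NADH": 1},
            gene="g_aldh", name="acetaldehyde dehydrogenase"),
        rxn("PDH", {"PYR": -1, "NAD": -1, "ACCOA": 1, "CO2": 1, "NADH": 1},
            gene="g_pdh1 or g_pdh2", name="pyruvate dehydrogenase"),
        rxn("PC", {"PYR": -1, "CO2": -1, "ATP": -1, "OAA": 1, "ADP": 1},
            gene="g_pc", name="pyruvate carboxylase"),
        rxn("CS", {"ACCOA": -1, "OAA": -1, "CIT": 1}, gene="g_cs",
            name="citrate synthase"),
        rxn("IDH", {"CIT": -1, "NAD": -1, "AKG": 1, "CO2": 1, "NADH": 1},
            gene="g_idh", name="isocitrate dehydrogenase (lumped)"),
        rxn("AKGDH", {"AKG": -1, "NAD": -1, "SUC": 1, "CO2": 1, "NADH": 1},
            gene="g_akgdh", name="2-oxoglutarate dehydrogenase (lumped)"),
        rxn("SDH", {"SUC": -1, "FAD": -1, "FUM": 1, "FADH2": 1},
            gene="g_sdh", name="succinate dehydrogenase"),
        rxn("FRD", {"FUM": -1, "NADH": -1, "SUC": 1, "NAD": 1},
            gene="g_frd", name="fumarate reductase (NADH)"),
        rxn("FUMR", {"FUM": -1, "MAL": 1}, lb=-BIG, gene="g_fum",
            name="fumarase"),
        rxn("MDH", {"MAL": -1, "NAD": -1, "OAA": 1, "NADH": 1},
            gene="g_mdh", name="malate dehydrogenase"),
        rxn("ICL", {"CIT": -1, "SUC": 1, "GLX": 1}, gene="g_icl",
            name="isocitrate lyase (lumped)"),
        rxn("MS", {"GLX": -1, "ACCOA": -1, "MAL": 1}, gene="g_ms",
            name="malate synthase"),
        # respiration
        rxn("ETC_NADH", {"NADH": -1, "O2": -0.5, "ADP": -2, "NAD": 1,
                         "ATP": 2}, gene="g_etc1 and g_etc2",
            name="ETC: NADH oxidation"),
        rxn("ETC_FADH", {"FADH2": -1, "O2": -0.5, "ADP": -1, "FAD": 1,
                         "ATP": 1}, gene="g_etc3",
            name="ETC: FADH2 oxidation"),
        # biomass precursors, maintenance, growth
        rxn("AABIO", {"PYR": -1, "NADH": -0.5, "ATP": -0.5, "AA": 1,
                      "NAD": 0.5, "ADP": 0.5}, gene="g_aa",
            name="amino-acid pool synthesis"),
        rxn("ATPM", {"ATP": -1, "ADP": 1}, lb=cfg.ngam, cat="maintenance",
            name="maintenance ATP (NGAM)"),
        rxn("BIOMASS", {"AA": -10, "OAA": -2.5, "ATP": -30, "PI": -pc,
                        "ADP": 30}, cat="biomass", name="biomass"),
    ]
    for acid in cfg.acids:
        met = _ACID_MET[acid]
        tag = ACID_TAGS[acid]
        n_h = protons_released(acid, cfg.pH)
        rxns.append(rxn(f"DISS_{tag}", {met: -1, f"{met}_e": 1,
                                        "H_e": n_h},
                        cat="dissociation",
                        name=f"{acid} dissociation/export"))
        rxns.append(rxn(f"EX_{tag}_e", {f"{met}_e": -1}, cat="exchange",
                        name=f"{acid} exchange"))

    return MetabolicModel(metabolites=mets, reactions=rxns,
                          objective_id="BIOMASS")


def toy_phases(config: ToyConfig | None = None
               ) -> tuple[PhaseParameterisation, PhaseParameterisation]:
    """Phase parameterisations matching :func:`build_toy_model` ids."""
    cfg = config or ToyConfig()
    common = dict(growth_id="BIOMASS", substrate_id="EX_glc_e",
                  phosphate_ext_id="EX_pi_e", phosphate_store_id="PISTORE",
                  ngam_id="ATPM", ngam=cfg.ngam, pH=cfg.pH)
    phase1 = PhaseParameterisation(
        phase=PHASE_STORAGE, objective_id="BIOMASS",
        bounds={
            "EX_glc_e": (-cfg.glucose_uptake_phase1, 0.0),
            "EX_pi_e": (-cfg.phosphate_uptake, 0.0),
            "PISTORE": (cfg.phosphate_storage_flux,
                        cfg.phosphate_storage_flux),
        }, **common)
    phase2 = PhaseParameterisation(
        phase=PHASE_PROTON, objective_id="EX_h_e",
        bounds={
            "EX_glc_e": (-cfg.glucose_uptake_phase2, 0.0),
            "EX_pi_e": (0.0, 0.0),
            "PISTORE": (-cfg.phosphate_release_flux, BIG),
        }, **common)
    return phase1, phase2


def acid_exchange_id(acid: str) -> str:
    try:
        return f"EX_{ACID_TAGS[acid]}_e"
    except KeyError:
        raise ModelError(f"unknown acid {acid!r}") from None


def carbon_imbalances(model: MetabolicModel,
                      tol: float = 1e-9) -> dict[str, float]:
    """Net carbon per internal (and transport) reaction; audit helper."""
    carbon = {m.id: m.carbon for m in model.metabolites}
    out = {}
    for r in model.reactions:
        if r.category not in ("internal", "transport"):
            continue
        net = sum(c * carbon.get(mid, 0) for mid, c in r.stoichiometry.items())
        if abs(net) > tol:
            out[r.id] = net
    return out
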