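import numpy as np
import pytest

import acidevo as ae


@pytest.fixture(scope="session")
def toy_config():
    return ae.ToyConfig()


@pytest.fixture(scope="session")
def toy_model(toy_config):
    return ae.build_toy_model(toy_config)


@pytest.fixture(scope="session")
def phases(toy_config):
    return ae.toy_phases(toy_config)


@pytest.fixture(scope="session")
def wildtype_trajectory(toy_model, phases, toy_config):
    p1, p2 = phases
    return ae.simulate_batch(toy_model, p1, p2, toy_config.batch)


@pytest.fixture(scope="session")
def constants(wildtype_trajectory):
    return ae.extract_constants(wildtype_trajectory)


@pytest.fixture(scope="session")
def problem(toy_model):
    return ae.FbaProblem(toy_model)


def make_context(toy_model, phases, constants, **overrides):
    """Evolution context with toy defaults; overrides go to GAConfig."""
    kwargs = dict(population_size=100, generations=10, seed=0,
                  target_acid="lactate", fitness_mode="adapted",
                  maxflux_cache=True)
    kwargs.update(overrides)
    cfg = ae.GAConfig(**kwargs)
    target = ae.acid_exchange_id(cfg.target_acid)
    return ae.EvolutionContext(toy_model, phases[1], constants, cfg, target)


@pytest.fixture(scope="session")
def lactate_context(toy_model, phases, constants):
    return make_context(toy_model, phases, constants)


@pytest.fixture(scope="session")
def citrate_context(toy_model, phases, constants):
    return make_context(toy_model, phases, constants,
                        target_acid="citrate", fitness_mode="simple")


def chain_model(n_mid: int = 2, cap: float = 10.0) -> ae.MetabolicModel:
    """e1 -> A -> ... -> e2 linear chain with source capacity ``cap``."""
    mets = [ae.Metabolite(f"M{i}", compartment="c") for i in range(n_mid)]
    rxns = [ae.Reaction("e_in", {"M0": 1}, lower_bound=0.0, upper_bound=cap,
                        category="exchange")]
    for i in range(n_mid - 1):
        rxns.append(ae.Reaction(f"r{i}", {f"M{i}": -1, f"M{i+1}": 1},
                                lower_bound=0.0, upper_bound=1000.0))
    rxns.append(ae.Reaction("e_out", {f"M{n_mid-1}": -1}, lower_bound=0.0,
                            upper_bound=1000.0, category="exchange"))
    return ae.MetabolicModel(metabolites=mets, reactions=rxns,
                             objective_id="e_out")
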