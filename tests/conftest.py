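import pytest

import methyloflux as mf
from methyloflux.model import Metabolite, Reaction


@pytest.fixture(scope="session")
def toy_model():
    return mf.build_toy_methanol_network()


@pytest.fixture(scope="session")
def glucose_conditions():
    return mf.SimulationConditions(fixed_uptakes={"EX_glc": 1.0}, ngam=1.0)


@pytest.fixture(scope="session")
def glucose_solution(toy_model, glucose_conditions):
    sol = mf.maximize_objective(toy_model, glucose_conditions)
    assert sol.optimal
    return sol


@pytest.fixture(scope="session")
def methanol_solution(toy_model):
    sol = mf.maximize_objective(
        toy_model, mf.SimulationConditions(fixed_uptakes={"EX_mthl": 1.0})
    )
    assert sol.optimal
    return sol


@pytest.fixture()
def chain_model():
    """EX_a -> a -> b -> biomass with 0.5 biomass per substrate."""
    mets = [Metabolite("a[e]"), Metabolite("a[c]"), Metabolite("b[c]")]
    rxns = [
        Reaction("EX_a", {"a[e]": -1.0}, True, lower_bound=-1.0,
                 upper_bound=0.0),
        Reaction("At", {"a[e]": -1.0, "a[c]": 1.0}, False),
        Reaction("R1", {"a[c]": -1.0, "b[c]": 1.0}, False, gpr="g1"),
        Reaction("BIOMASS", {"b[c]": -2.0}, False),
    ]
    return mf.MetabolicModel(mets, rxns, "BIOMASS", name="chain")
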