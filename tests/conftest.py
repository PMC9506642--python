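import pytest

from dendrosim.cable_engine import (
    Channel,
    CompartmentalModel,
    settle,
)
from dendrosim.mechanisms import (
    CaPoolParams,
    ConductanceProfile,
    ProfileForm,
    calva_mechanism,
    generic_mechanism,
    ih_hay_mechanism,
)
from dendrosim.morphology import Section, SectionTree
from dendrosim.synthdata import ScenarioSpec, make_scenario


def soma_profile(value: float) -> ConductanceProfile:
    return ConductanceProfile(
        forms=(("soma", ProfileForm(kind="constant", value=value)),)
    )


def passive_single_compartment(g_pas: float = 5e-5, e_pas: float = -70.0,
                               diam: float = 20.0) -> CompartmentalModel:
    tree = SectionTree([Section(0, -1, 0.0, "soma", diam, diam, diam)])
    chans = {"leak": Channel(generic_mechanism("leak", (), erev=e_pas),
                             soma_profile(g_pas))}
    return CompartmentalModel(tree, chans, v_init=e_pas)


def distal_compartment(ih_density: float = 0.012,
                       calva_density: float = 0.0187) -> CompartmentalModel:
    """Isolated distal-dendrite-like compartment: leak + Ih + LVA + Ca pool."""
    tree = SectionTree([Section(0, -1, 0.0, "soma", 20, 20, 20)])
    chans = {
        "leak": Channel(generic_mechanism("leak", (), erev=-88.0),
                        soma_profile(4e-5)),
        "ih": Channel(ih_hay_mechanism(), soma_profile(ih_density)),
        "calva": Channel(calva_mechanism(), soma_profile(calva_density)),
    }
    return CompartmentalModel(tree, chans, ca_pool=CaPoolParams(), v_init=-75.0)


@pytest.fixture(scope="session")
def hotzone_model():
    return make_scenario(ScenarioSpec())


@pytest.fixture(scope="session")
def hotzone_blocked(hotzone_model):
    return hotzone_model.blocked("ih", 0.0)


@pytest.fixture(scope="session")
def nohz_model():
    return make_scenario(ScenarioSpec(hot_zone_on=False))


@pytest.fixture(scope="session")
def settled(hotzone_model):
    return settle(hotzone_model, 1500.0)


@pytest.fixture(scope="session")
def settled_blocked(hotzone_blocked):
    return settle(hotzone_blocked, 1500.0)


@pytest.fixture(scope="session")
def small_scenario():
    """Coarser, cheaper scenario for protocol mechanics tests."""
    return make_scenario(ScenarioSpec(max_seg_length=50.0))
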