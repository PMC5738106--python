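import pytest

from midasim.protocol import FoodSpec, default_sampling_plan, plan_fluid_volumes
from midasim.synthetic import preset_design, run_design, standard_schedule


@pytest.fixture(scope="session")
def basic_design():
    return preset_design("rice_cream_basic")


@pytest.fixture(scope="session")
def premium_design():
    return preset_design("rice_cream_premium")


@pytest.fixture(scope="session")
def basic_run(basic_design):
    """Deterministic single run of the unfermented rice cream."""
    return run_design(basic_design)


@pytest.fixture(scope="session")
def premium_run(premium_design):
    return run_design(premium_design)


@pytest.fixture(scope="session")
def standard_plan():
    return plan_fluid_volumes(45.0, 10.0, 8, 10.0)


@pytest.fixture()
def small_food():
    return FoodSpec(name="test food", portion_volume_ml=45.0, starch_g=1.0,
                    glucose_g=0.01, initial_pH=6.5)
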