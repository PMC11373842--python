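import pytest

from foodprint import (
    ScenarioConfig,
    make_mini_food_system,
    mini_reference_diet,
    run_single,
)


@pytest.fixture(scope="session")
def mini_params():
    return make_mini_food_system()


@pytest.fixture(scope="session")
def reference_diet():
    return mini_reference_diet()


@pytest.fixture(scope="session")
def mini_scenario():
    return ScenarioConfig(population_size=100.0, trade_mode="closed")


@pytest.fixture(scope="session")
def reference_result(mini_params, reference_diet, mini_scenario):
    return run_single(reference_diet, mini_params, mini_scenario)
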