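import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from sccarbon import climate as climate_mod
from sccarbon import scenarios as scenarios_mod


@pytest.fixture(scope="session")
def small_config():
    """Default anchors, few countries: world-level behaviour is unchanged."""
    return scenarios_mod.GeneratorConfig(n_countries=8)


@pytest.fixture(scope="session")
def draw(small_config):
    return scenarios_mod.sample_scenario(small_config, 42)


@pytest.fixture(scope="session")
def climate_params():
    return climate_mod.ClimateParams()


@pytest.fixture(scope="session")
def climate_path(draw, climate_params):
    return climate_mod.run_climate(draw, climate_params)
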