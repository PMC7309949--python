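import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from taicea import GeneratorConfig, MortalityTable, default_parameters, generate_survey
from taicea.mapping import ValueSet

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def base_params():
    return default_parameters()


@pytest.fixture(scope="session")
def value_set():
    return ValueSet.packaged()


@pytest.fixture(scope="session")
def survey_5000():
    """One large synthetic survey shared by the recovery tests."""
    return generate_survey(GeneratorConfig(n=5000, seed=3))


def constant_mortality_table(q_annual: float) -> MortalityTable:
    """A flat life table for hand-computable scenarios."""
    ages = np.arange(0, 121)
    df = pd.DataFrame(
        {"age": ages, "qx_male": q_annual, "qx_female": q_annual}
    )
    return MortalityTable(df)


@pytest.fixture
def flat_mortality():
    return constant_mortality_table
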