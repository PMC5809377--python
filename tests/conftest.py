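import numpy as np
import pytest

from pm25burden.grids import GriddedField, GridSpec
from pm25burden.synthetic import (
    SyntheticConfig,
    gen_age_structure,
    gen_baseline_mortality,
    gen_ier_parameters,
    gen_life_table,
    gen_pm25_control,
    gen_population,
    gen_sector_off_fields,
)


@pytest.fixture(scope="session")
def spec10():
    return GridSpec(n_lat=10, n_lon=10)


@pytest.fixture(scope="session")
def cfg():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def control_weekly(spec10, cfg):
    return gen_pm25_control(spec10, cfg)


@pytest.fixture(scope="session")
def control(control_weekly):
    return control_weekly[0]


@pytest.fixture(scope="session")
def scenarios(control, cfg):
    return gen_sector_off_fields(control, cfg)


@pytest.fixture(scope="session")
def population(spec10, cfg):
    return gen_population(spec10, 1_000_000, cfg)


@pytest.fixture(scope="session")
def ensemble():
    return gen_ier_parameters(n_draws=200, seed=3)


@pytest.fixture(scope="session")
def baseline_mortality():
    return gen_baseline_mortality()


@pytest.fixture(scope="session")
def life_table():
    return gen_life_table()


@pytest.fixture(scope="session")
def ages():
    return gen_age_structure()


def uniform_field(spec: GridSpec, value: float) -> GriddedField:
    return GriddedField(np.full(spec.shape, float(value)), spec)
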