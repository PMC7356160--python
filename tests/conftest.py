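import pytest

from cdintake.concentrations import ConcentrationTable
from cdintake.mapping import default_mapping
from cdintake.synthetic import generate_cohort, load_preset


@pytest.fixture(scope="session")
def table():
    return ConcentrationTable.default()


@pytest.fixture(scope="session")
def rules(table):
    return default_mapping(table)


@pytest.fixture(scope="session")
def area_b_params():
    return load_preset("area_B")


@pytest.fixture(scope="session")
def area_a_params():
    return load_preset("area_A")


@pytest.fixture(scope="session")
def area_b_cohort(area_b_params, table):
    return generate_cohort(area_b_params, seed=1, table=table)
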