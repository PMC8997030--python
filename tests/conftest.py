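import pytest

from lungscreen_cea import (
    SyntheticLifeTableSpec,
    bundled_life_table,
    default_parameters,
    default_strategies,
    make_life_table,
)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def strategies(params):
    return default_strategies(params)


@pytest.fixture(scope="session")
def ct(strategies):
    return strategies[0]


@pytest.fixture(scope="session")
def ct_ai(strategies):
    return strategies[1]


@pytest.fixture(scope="session")
def life_table():
    return bundled_life_table()


@pytest.fixture(scope="session")
def flat_life_table():
    """q = 0.02 at every age: geometric-survival closed forms apply."""
    return make_life_table(SyntheticLifeTableSpec(model="flat", q0=0.02))


@pytest.fixture(scope="session")
def immortal_life_table():
    """q = 0 everywhere: no background mortality."""
    return make_life_table(SyntheticLifeTableSpec(model="flat", q0=0.0))
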