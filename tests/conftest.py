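import pytest

from acs_cea import default_configs
from acs_cea.synthetic import bundled_life_table


@pytest.fixture(scope="session")
def configs():
    return default_configs()


@pytest.fixture(scope="session")
def overall_config(configs):
    return configs["overall"]


@pytest.fixture(scope="session")
def german_lt():
    return bundled_life_table("german_2009")


@pytest.fixture(scope="session")
def synth_lt():
    return bundled_life_table("synthetic_default")
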