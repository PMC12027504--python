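import pytest

from chctax.catalog import load_catalog, load_population_profiles
from chctax.retention import build_ladder


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def population_profiles():
    return load_population_profiles()


@pytest.fixture(scope="session")
def alkane_ladder(catalog):
    return build_ladder(catalog.alkane_ladder_components())
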