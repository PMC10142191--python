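import numpy as np
import pytest

from c13pos.fragment_library import load_fragment_table, registry_index
from c13pos.isotope_correction import IsotopeTable


@pytest.fixture(scope="session")
def registry():
    return load_fragment_table()


@pytest.fixture(scope="session")
def registry_by_id(registry):
    return registry_index(registry)


@pytest.fixture(scope="session")
def isotope_table():
    return IsotopeTable()


@pytest.fixture
def rng():
    return np.random.default_rng(20230323)
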