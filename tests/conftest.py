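import pytest

from krascope.refmodel import synthetic_locus
from krascope.synthetic_data import default_index_table


@pytest.fixture(scope="session")
def locus():
    return synthetic_locus()


@pytest.fixture(scope="session")
def index_table():
    return default_index_table()
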