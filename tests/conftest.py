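import pytest

from pcbdechlor.congeners import get_table
from pcbdechlor.pathways import build_network


@pytest.fixture(scope="session")
def table():
    return get_table()


@pytest.fixture(scope="session")
def meta_network():
    return build_network(allowed={"meta"})


@pytest.fixture(scope="session")
def meta_para_network():
    return build_network(allowed={"meta", "para"})


@pytest.fixture(scope="session")
def full_network():
    return build_network()
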