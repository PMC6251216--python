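import pytest

from bsamap.fixtures import (
    KAN1_DOMAINS,
    KAN1_EVENT,
    make_funnel_fixture,
    make_kan1_like_gene,
)


@pytest.fixture(scope="session")
def kan1_gene():
    return make_kan1_like_gene()


@pytest.fixture(scope="session")
def kan1_event():
    return KAN1_EVENT


@pytest.fixture(scope="session")
def kan1_domains():
    return KAN1_DOMAINS


@pytest.fixture(scope="session")
def funnel():
    return make_funnel_fixture(seed=7)
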