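import warnings

import pytest
from hypothesis import HealthCheck, settings

from contourgraph import fixtures, groups

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def karate_like():
    """34-node / 78-edge network with 6 overlapping communities A-F."""
    return fixtures.make_karate_like()


@pytest.fixture(scope="session")
def module_fixture():
    """Network with a planted 17-node, 18-edge Module=small subgraph."""
    return fixtures.make_module_fixture()


@pytest.fixture(scope="session")
def karate_sets(karate_like):
    network, table = karate_like
    sets = groups.generate_groups(network, table, ["Community"])
    return groups.select_groups(sets, ["A", "B", "C", "D", "E", "F"])


@pytest.fixture()
def quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
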