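import pytest

from wetflux import default_network, load_endpoints
from wetflux.reaction_network import active_network, condition_flags


@pytest.fixture(scope="session")
def net():
    return default_network()


@pytest.fixture(scope="session")
def endpoint_table():
    return load_endpoints()


@pytest.fixture(scope="session")
def anoxic_net(net):
    return active_network(net, oxic=False, sulfate_added=False)


@pytest.fixture(scope="session")
def condition_endpoints(endpoint_table):
    """Endpoint means per condition, keyed metabolite -> mmole/g dry soil."""
    out = {}
    for cond in ("S-O-", "S+O-", "S-O+", "S+O+"):
        sub = endpoint_table[endpoint_table["condition"] == cond]
        out[cond] = dict(zip(sub["metabolite_id"], sub["mean_mmol_per_g_dry_soil"]))
    return out


def active_for(net, condition):
    sulfate, oxic = condition_flags(condition)
    return active_network(net, oxic=oxic, sulfate_added=sulfate)
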