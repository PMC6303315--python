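import logging

import pytest

import emuflux as ef

logging.getLogger("emuflux").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def network():
    return ef.reference_network()


@pytest.fixture(scope="session")
def tracer(network):
    return ef.default_tracer(network)


@pytest.fixture(scope="session")
def control():
    return ef.make_scenario("control")


@pytest.fixture(scope="session")
def inhibited():
    return ef.make_scenario("phgdh_inhibited")


@pytest.fixture(scope="session")
def control_mids(control, network, tracer):
    """Noise-free single-replicate MIDs of every balanced pool."""
    return ef.simulate_mid_dataset(control, network, tracer, n_replicates=1)
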