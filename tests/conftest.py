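import numpy as np
import pytest

import phenoprop as pp


@pytest.fixture(scope="session")
def world():
    """Default synthetic world shared by read-only tests."""
    return pp.generate_world(pp.SyntheticWorldConfig(rng_seed=1))


@pytest.fixture(scope="session")
def propagator(world):
    return pp.NetworkPropagator().fit(world.network)


@pytest.fixture
def path_network():
    """5-node path A–B–C–D–E with unit weights."""
    return pp.InteractionNetwork.from_edges(
        [("A", "B", 1.0), ("B", "C", 1.0), ("C", "D", 1.0), ("D", "E", 1.0)])
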