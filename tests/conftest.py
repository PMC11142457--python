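"""Shared fixtures: small seeded networks and their distance structures."""

import numpy as np
import pytest

from conncomm import (DirectedNetwork, build_distance_structure,
                      generate_dense_weighted_network, generate_hub_network,
                      toy_transition_graph)


@pytest.fixture(scope="session")
def cycle3():
    """Binary directed 3-cycle 0 -> 1 -> 2 -> 0."""
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 2] = w[2, 0] = 1.0
    return DirectedNetwork(w)


@pytest.fixture(scope="session")
def toy():
    """(network, current, destination): three out-neighbors at geodesic
    distances 1, 2, 3 from the destination."""
    return toy_transition_graph()


@pytest.fixture(scope="session")
def two_node():
    """0 <-> 1: the minimal strongly connected network."""
    w = np.array([[0.0, 1.0], [1.0, 0.0]])
    return DirectedNetwork(w)


@pytest.fixture(scope="session")
def small_hub():
    """121-node sparse binary hub network at connectome-like density 0.07."""
    return generate_hub_network(n_nodes=121, n_edges=1020, hub_count=5, seed=3)


@pytest.fixture(scope="session")
def small_hub_ds(small_hub):
    return build_distance_structure(small_hub)


@pytest.fixture(scope="session")
def tiny_hub():
    """12-node network used for exhaustive / Monte-Carlo oracle checks."""
    return generate_hub_network(n_nodes=12, n_edges=30, hub_count=2, seed=5)


@pytest.fixture(scope="session")
def tiny_hub_ds(tiny_hub):
    return build_distance_structure(tiny_hub)


@pytest.fixture(scope="session")
def dense_weighted():
    """Dense weighted fixture emulating a tracer-strength connectome."""
    return generate_dense_weighted_network(seed=2)
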