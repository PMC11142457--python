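"""Synthetic fixture networks with the structure the analyses assume.

Three generators cover the regimes the simulations probe, so that every
pipeline stage is testable without any external download:

- :func:`generate_hub_network` — a sparse binary directed network (default
  242 nodes, 4,090 edges, density 0.070) with a small set of high in-degree
  hubs, the regime where packetization under slow strategies piles traffic
  into hub bottlenecks.
- :func:`generate_dense_weighted_network` — a dense weighted directed
  network (default 213 nodes, density 0.373) whose hubs are visible in
  in-strength but washed out in binarized in-degree, and whose binarized
  geodesics concentrate on lengths {1, 2}.
- :func:`toy_transition_graph` — the 5-node illustration of the biased
  random walk: a current node with three out-neighbors at geodesic
  distances 1, 2 and 3 from the destination.

All generators guarantee strong connectivity (a random Hamiltonian cycle is
laid first) and are reproducible from their seed.
"""

from __future__ import annotations

import numpy as np

from .network_model import DirectedNetwork


def _hamiltonian_cycle(n_nodes: int, rng: np.random.Generator) -> tuple[np.ndarray, set]:
    """A random directed cycle through all nodes; guarantees strong
    connectivity of anything built on top of it."""
    order = rng.permutation(n_nodes)
    w = np.zeros((n_nodes, n_nodes))
    edges = set()
    for u, v in zip(order, np.roll(order, -1)):
        w[u, v] = 1.0
        edges.add((int(u), int(v)))
    return w, edges


def generate_hub_network(
    n_nodes: int = 242,
    n_edges: int = 4090,
    hub_count: int = 10,
    hub_in_degree_boost: float = 6.0,
    seed: int = 0,
) -> DirectedNetwork:
    """Sparse binary directed network with heavy right-tailed in-degree.

    ``hub_count`` designated hubs attract in-edges with sampling weight
    ``1 + hub_in_degree_boost`` against 1 for ordinary nodes, so the default
    boost puts hub in-degrees around 5-6x the median — a few clearly
    dominant integrator nodes, as in sparse tracer-derived cortical
    networks. ``hub_in_degree_boost=0`` degrades gracefully to a uniform
    random digraph (plus the connectivity cycle).
    """
    if n_edges > n_nodes * (n_nodes - 1):
        raise ValueError("more edges requested than off-diagonal ordered pairs")
    if n_edges < n_nodes:
        raise ValueError("need at least n_nodes edges for the connectivity cycle")
    if hub_count < 0 or hub_in_degree_boost < 0:
        raise ValueError("hub_count and hub_in_degree_boost must be nonnegative")
    rng = np.random.default_rng(seed)
    target_w = np.ones(n_nodes)
    hubs = rng.choice(n_nodes, size=hub_count, replace=False) if hub_count else np.array([], int)
    target_w[hubs] = 1.0 + hub_in_degree_boost
    expected_hub_in = n_edges * target_w.max() / target_w.sum()
    if expected_hub_in > 0.8 * (n_nodes - 1):
        raise ValueError("infeasible degree demands: hub in-degree target too large")
    target_p = target_w / target_w.sum()

    w, edges = _hamiltonian_cycle(n_nodes, rng)
    remaining = n_edges - n_nodes
    while remaining > 0:
        batch = max(64, 2 * remaining)
        srcs = rng.integers(n_nodes, size=batch)
        dsts = rng.choice(n_nodes, size=batch, p=target_p)
        for u, v in zip(srcs.tolist(), dsts.tolist()):
            if u == v or (u, v) in edges:
                continue
            edges.add((u, v))
            w[u, v] = 1.0
            remaining -= 1
            if remaining == 0:
                break
    net = DirectedNetwork(w)
    assert net.n_edges == n_edges
    return net


def generate_dense_weighted_network(
    n_nodes: int = 213,
    density: float = 0.373,
    hub_count: int = 10,
    hub_strength_boost: float = 6.0,
    weight_sigma: float = 1.0,
    seed: int = 0,
    max_retries: int = 100,
) -> DirectedNetwork:
    """Dense weighted directed network with in-strength (not in-degree) hubs.

    Edge placement is uniform, so at density ~0.37 the binarized in-degree
    is tightly binomial (its minimum is a large fraction of N and binarized
    geodesics concentrate on lengths 1-2). Edge weights are log-normal with
    shape ``weight_sigma``; incoming weights of ``hub_count`` hub nodes are
    multiplied by ``hub_strength_boost``, producing hubs visible only after
    weighting — the signature of dense tracer-strength networks. Weights are
    raw projection-strength-like values; normalize into (0, 1) with
    :func:`conncomm.network_model.normalize_weights` before simulation.
    """
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    n_edges = int(round(density * n_nodes * (n_nodes - 1)))
    if n_edges < n_nodes:
        raise ValueError("density too low to keep the network strongly connected")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        w, edges = _hamiltonian_cycle(n_nodes, rng)
        flat = rng.permutation(n_nodes * (n_nodes - 1))
        need = n_edges - n_nodes
        for f in flat:
            if need == 0:
                break
            u = int(f // (n_nodes - 1))
            v = int(f % (n_nodes - 1))
            if v >= u:
                v += 1
            if (u, v) in edges:
                continue
            edges.add((u, v))
            w[u, v] = 1.0
            need -= 1
        src, dst = np.nonzero(w)
        w[src, dst] = rng.lognormal(mean=0.0, sigma=weight_sigma, size=src.size)
        hubs = rng.choice(n_nodes, size=hub_count, replace=False)
        w[:, hubs] *= hub_strength_boost
        net = DirectedNetwork(w)
        if net.is_strongly_connected():
            assert net.n_edges == n_edges
            return net
    raise RuntimeError("could not generate a strongly connected dense network")


def toy_transition_graph() -> tuple[DirectedNetwork, int, int]:
    """5-node binary graph illustrating biased-random-walk transition
    probabilities: returns (network, current node, destination node) where
    the current node's three out-neighbors sit at geodesic distances 1, 2
    and 3 from the destination."""
    # nodes: 0 = current, 1..3 = neighbors at distance 1/2/3, 4 = destination
    w = np.zeros((5, 5))
    for u, v in [(0, 1), (0, 2), (0, 3), (1, 4), (2, 1), (3, 2), (4, 0)]:
        w[u, v] = 1.0
    return DirectedNetwork(w, labels=("current", "near", "mid", "far", "dest")), 0, 4
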