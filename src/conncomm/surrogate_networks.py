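"""Rewired null networks: fully randomized and degree-preserving surrogates.

Fully randomized surrogates keep only the node and edge counts, scattering
edges uniformly over off-diagonal ordered pairs (hubs vanish; the in-degree
distribution becomes near-binomial). Degree-preserving surrogates keep every
node's in- and out-degree exactly, via repeated double-edge swaps
(a->b, c->d) => (a->d, c->b). Both are regenerated until strongly connected
so the simulator can use them.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .network_model import DirectedNetwork


class RewireError(RuntimeError):
    """Retry budget exhausted without a strongly connected surrogate."""


def rewire_full(net: DirectedNetwork, seed: int, max_retries: int = 1000) -> DirectedNetwork:
    """Place the network's E edges uniformly at random (no self-loops, no
    duplicates); weighted nets get their weight multiset randomly reassigned
    to the new edges. Retries until strongly connected."""
    n = net.n_nodes
    w = net.weights
    src0, dst0 = np.nonzero(w)
    weights = w[src0, dst0]
    n_edges = src0.size
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        # sample off-diagonal ordered pairs without replacement
        flat = rng.choice(n * (n - 1), size=n_edges, replace=False)
        src = flat // (n - 1)
        dst = flat % (n - 1)
        dst = np.where(dst >= src, dst + 1, dst)
        new = np.zeros_like(w)
        new[src, dst] = rng.permutation(weights)
        cand = replace(net, weights=new)
        if cand.is_strongly_connected():
            return cand
    raise RewireError(f"no strongly connected full rewiring found in {max_retries} tries")


def rewire_degree_preserving(
    net: DirectedNetwork,
    seed: int,
    swaps_per_edge: int = 10,
    max_retries: int = 50,
) -> DirectedNetwork:
    """Randomize edge placement while keeping every node's in- and
    out-degree, by ``swaps_per_edge * E`` accepted double-edge swaps.

    A swap picks two edges a->b, c->d and rewires them to a->d, c->b,
    rejected when it would create a self-loop or a duplicate edge. Each edge
    carries its weight through swaps, preserving the weight multiset (in-
    and out-strength are not preserved for weighted nets). The whole pass is
    retried from scratch if the result is not strongly connected.
    """
    if swaps_per_edge == 0:
        return replace(net, weights=net.weights.copy())
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        cand = _swap_pass(net, rng, swaps_per_edge)
        if cand.is_strongly_connected():
            return cand
    raise RewireError(
        f"no strongly connected degree-preserving rewiring found in {max_retries} passes")


def _swap_pass(net: DirectedNetwork, rng: np.random.Generator,
               swaps_per_edge: int) -> DirectedNetwork:
    w = net.weights.copy()
    src, dst = np.nonzero(w)
    edges = list(zip(src.tolist(), dst.tolist()))
    edge_set = set(edges)
    n_edges = len(edges)
    target = swaps_per_edge * n_edges
    accepted = 0
    guard = 200 * target  # degenerate graphs can reject almost every proposal
    tries = 0
    while accepted < target and tries < guard:
        tries += 1
        i, j = rng.integers(n_edges, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if a == d or c == b:  # would create a self-loop
            continue
        if (a, d) in edge_set or (c, b) in edge_set:
            continue
        edge_set.discard((a, b))
        edge_set.discard((c, d))
        edge_set.add((a, d))
        edge_set.add((c, b))
        edges[i] = (a, d)
        edges[j] = (c, b)
        wab, wcd = w[a, b], w[c, d]
        w[a, b] = 0.0
        w[c, d] = 0.0
        w[a, d] = wab
        w[c, b] = wcd
        accepted += 1
    return replace(net, weights=w)


def surrogate_batch(
    net: DirectedNetwork,
    kind: str,
    n_surrogates: int = 100,
    master_seed: int = 0,
    **kwargs,
) -> list[DirectedNetwork]:
    """A reproducible batch of surrogates from one master seed. The same
    batch is meant to be reused across every strategy x switching condition
    of an experiment, so generate once and pass around."""
    fn = {"full": rewire_full, "degree": rewire_degree_preserving}.get(kind)
    if fn is None:
        raise ValueError(f"unknown surrogate kind {kind!r}; expected 'full' or 'degree'")
    seeds = np.random.SeedSequence(master_seed).generate_state(n_surrogates) % (2**31)
    return [fn(net, seed=int(s), **kwargs) for s in seeds]
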