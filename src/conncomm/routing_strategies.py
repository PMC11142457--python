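"""Next-hop decision rules for signal propagation on directed networks.

Six strategies are supported, spanning the trade-off between communication
speed and information requirements:

- ``RW``      random walk: uniform over out-neighbors (binary networks) or
              proportional to edge weights (weighted networks); needs no
              knowledge of the network.
- ``SP``      shortest path: uniform over the out-neighbors that lie on a
              shortest path to the destination; needs global topology.
- ``iRW_d``   informed RW, direct rule: hop straight to the destination when
              it is an out-neighbor, otherwise RW.
- ``iRW_a``   informed RW, avoidance rule: prefer out-neighbors whose server
              is idle; if none, those with the shortest buffer queue; ties
              broken in the manner of RW.
- ``iRW_a+d`` direct rule first, then the avoidance rule.
- ``bRW``     biased RW with control parameter c >= 0:
              p(i -> j | D) ∝ exp(-(c (d_ij + g_jD) + d_ij)),
              interpolating from RW (c = 0) to SP (c -> inf).

Edge distances are d_ij = 1 on binary networks and d_ij = log(1/w_ij) > 0 on
weighted networks with w_ij in (0, 1); g_jD is the geodesic distance from j
to the destination D under d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .network_model import DirectedNetwork

STRATEGY_KINDS = ("RW", "SP", "iRW_a", "iRW_d", "iRW_a+d", "bRW")

#: The default c-grid for bRW sweeps: 28 values log-spanning three decades.
BRW_C_GRID: tuple[float, ...] = tuple(
    round(0.01 * k, 2) for k in range(1, 10)
) + tuple(round(0.1 * k, 1) for k in range(1, 10)) + tuple(float(k) for k in range(1, 11))

_GEO_TOL = 1e-9


@dataclass(frozen=True)
class StrategySpec:
    """A propagation strategy selection: kind plus bRW's bias parameter."""

    kind: str
    c: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in STRATEGY_KINDS:
            raise ValueError(f"unknown strategy {self.kind!r}; expected one of {STRATEGY_KINDS}")
        if self.kind == "bRW":
            if self.c is None or self.c < 0:
                raise ValueError("bRW requires a bias parameter c >= 0")
        elif self.c is not None:
            raise ValueError(f"c is only meaningful for bRW, not {self.kind}")

    @property
    def label(self) -> str:
        return f"bRW(c={self.c:g})" if self.kind == "bRW" else self.kind


@dataclass
class DistanceStructure:
    """Edge distances, geodesics and next-hop machinery for one network.

    ``d[i, j]`` is the edge distance (inf where no edge exists); ``g[j, D]``
    the geodesic distance from j to D. ``neighbors[i]`` is the array of
    out-neighbors of i, with ``cum_weights[i]`` the cumulative edge weights
    for weight-proportional sampling.
    """

    d: np.ndarray
    g: np.ndarray
    neighbors: list[np.ndarray]
    cum_weights: list[np.ndarray]
    weighted: bool
    _sp_cache: dict = field(default_factory=dict, repr=False)
    _brw_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.d.shape[0]

    def sp_next_hops(self, i: int, D: int) -> np.ndarray:
        """Out-neighbors of i on a shortest i -> D path.

        j qualifies iff d_ij + g_jD = g_iD (within tolerance for weighted
        distances).
        """
        key = (i, D)
        hops = self._sp_cache.get(key)
        if hops is None:
            nb = self.neighbors[i]
            total = self.d[i, nb] + self.g[nb, D]
            hops = nb[total <= self.g[i, D] + _GEO_TOL]
            self._sp_cache[key] = hops
        return hops

    def brw_cum_probs(self, i: int, D: int, c: float) -> tuple[np.ndarray, np.ndarray]:
        """(neighbors, cumulative transition probabilities) for bRW at i."""
        key = (i, D, c)
        cached = self._brw_cache.get(key)
        if cached is None:
            nb = self.neighbors[i]
            p = brw_transition_probs(i, D, c, self)
            cached = (nb, np.cumsum(p))
            self._brw_cache[key] = cached
        return cached


def build_distance_structure(net: DirectedNetwork) -> DistanceStructure:
    """Compute edge distances and all-pairs geodesics for a network.

    Binary networks use unit edge distances; weighted networks (weights
    already normalized into (0, 1)) use d = log(1/w). Geodesics come from
    Dijkstra on the sparse distance matrix.
    """
    net.require_strongly_connected()
    w = net.weights
    weighted = not net.is_binary
    if weighted:
        if np.any(w >= 1):
            raise ValueError("weighted networks must be normalized into (0, 1) first")
        with np.errstate(divide="ignore"):
            d = np.where(w > 0, -np.log(np.maximum(w, 1e-300)), np.inf)
    else:
        d = np.where(w > 0, 1.0, np.inf)
    sparse_d = csr_matrix(np.where(np.isinf(d), 0.0, d))
    # dijkstra treats explicit zeros as absent edges; distances here are
    # strictly positive so no edge is lost.
    g = dijkstra(sparse_d, directed=True)
    neighbors = [np.flatnonzero(w[i]) for i in range(net.n_nodes)]
    cum_weights = [np.cumsum(w[i, nb]) for i, nb in enumerate(neighbors)]
    return DistanceStructure(d=d, g=g, neighbors=neighbors, cum_weights=cum_weights,
                             weighted=weighted)


def brw_transition_probs(i: int, D: int, c: float, ds: DistanceStructure) -> np.ndarray:
    """Biased-random-walk transition probabilities from i toward D.

    p_ij ∝ exp(-(c (d_ij + g_jD) + d_ij)), normalized over the out-neighbors
    of i. The maximum exponent is subtracted before exponentiation, which
    leaves the probabilities unchanged but avoids underflow at large c.
    """
    if i == D:
        raise ValueError("no transition needed: already at the destination")
    nb = ds.neighbors[i]
    if nb.size == 0:
        raise ValueError(f"node {i} has no out-neighbors")
    expo = -(c * (ds.d[i, nb] + ds.g[nb, D]) + ds.d[i, nb])
    expo -= expo.max()
    p = np.exp(expo)
    return p / p.sum()


class Router:
    """Per-run next-hop chooser; holds the strategy, distances and caches.

    ``nodes`` passed to :meth:`choose` is any sequence whose elements expose
    ``server`` (None when idle) and ``buffer`` (sized container) — the
    occupancy view iRW_a reads at the instant of the routing decision.
    """

    def __init__(self, spec: StrategySpec, ds: DistanceStructure):
        self.spec = spec
        self.ds = ds
        self._dest_adjacent: dict[tuple[int, int], bool] = {}

    def _rw_pick(self, nb: np.ndarray, cum: np.ndarray | None, rng: np.random.Generator) -> int:
        if cum is None:
            return int(nb[rng.integers(nb.size)])
        return int(nb[np.searchsorted(cum, rng.random() * cum[-1])])

    def _rw_among(self, cand: np.ndarray, current: int, rng: np.random.Generator) -> int:
        """Pick among candidate neighbors 'in the manner of RW'."""
        if cand.size == 1:
            return int(cand[0])
        if self.ds.weighted:
            w = np.exp(-self.ds.d[current, cand])  # back to edge weights
            cum = np.cumsum(w)
            return int(cand[np.searchsorted(cum, rng.random() * cum[-1])])
        return int(cand[rng.integers(cand.size)])

    def choose(self, destination: int, current: int, nodes, rng: np.random.Generator) -> int:
        ds = self.ds
        nb = ds.neighbors[current]
        kind = self.spec.kind
        if kind == "RW":
            return self._rw_pick(nb, ds.cum_weights[current] if ds.weighted else None, rng)
        if kind == "SP":
            hops = ds.sp_next_hops(current, destination)
            return int(hops[rng.integers(hops.size)]) if hops.size > 1 else int(hops[0])
        if kind == "bRW":
            cnb, cum = ds.brw_cum_probs(current, destination, self.spec.c)
            return int(cnb[np.searchsorted(cum, rng.random() * cum[-1])])
        # informed RW variants
        if kind in ("iRW_d", "iRW_a+d"):
            key = (current, destination)
            adj = self._dest_adjacent.get(key)
            if adj is None:
                adj = bool(np.isfinite(ds.d[current, destination]))
                self._dest_adjacent[key] = adj
            if adj:
                return destination
            if kind == "iRW_d":
                return self._rw_pick(nb, ds.cum_weights[current] if ds.weighted else None, rng)
        # avoidance rule (iRW_a, or iRW_a+d with destination not adjacent)
        idle = np.fromiter((nodes[j].server is None for j in nb), dtype=bool, count=nb.size)
        if idle.any():
            return self._rw_among(nb[idle], current, rng)
        qlens = np.fromiter((len(nodes[j].buffer) for j in nb), dtype=np.int64, count=nb.size)
        return self._rw_among(nb[qlens == qlens.min()], current, rng)


def next_hop(
    spec: StrategySpec,
    destination: int,
    current: int,
    nodes,
    ds: DistanceStructure,
    rng: np.random.Generator,
) -> int:
    """One next-hop decision; convenience wrapper around :class:`Router`."""
    if current == destination:
        raise ValueError("signal is already at its destination")
    return Router(spec, ds).choose(destination, current, nodes, rng)
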