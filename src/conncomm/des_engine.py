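"""Discrete-event queueing simulation of signal propagation on a connectome.

Nodes are single servers with a finite LIFO buffer. Signals (whole messages,
or the n packets a message is split into under packet switching) are
generated as one network-wide Poisson process, hop node-to-node under a
propagation strategy, queue when a server is busy, and are removed on
reaching their destination. A full buffer ejects its oldest occupant. The
run stops once a target number of messages / complete packet sets have been
delivered, and reports that duration together with per-node time-averaged
communication metrics.

Event mechanics (one heapq loop, one seeded generator per run):

1. Generations form a Poisson process of rate ``lam``; each generation draws
   a uniform source, a uniform destination among the other nodes, and
   injects 1 message or n simultaneous packets (in packet-index order) at
   the source.
2. An arriving signal enters the node's server if idle, else is pushed to
   the buffer front; overflow ejects the buffer back (the oldest signal),
   which counts as dropped.
3. Service times are exponential: rate ``mu`` for messages, ``n * mu`` for
   packets (buffer capacity likewise H vs n*H — a packet is 1/n the size of
   a message). On completion the signal is routed and transmitted
   instantaneously, then the freed server pulls the buffer front (LIFO) or
   back (FIFO).
4. Delivery at the destination removes the signal immediately, with no
   service and no buffer slot.

Draw order per event is fixed (interarrival, source, destination at a
generation; routing decision, then service-time draws in arrival-before-
requeue order at a service completion), so runs are bit-reproducible from
their seed. Message switching is simulated as the n = 1 special case of
packet switching, which makes the two architectures trajectory-identical at
n = 1 by construction.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .network_model import DirectedNetwork
from .routing_strategies import DistanceStructure, Router, StrategySpec, build_distance_structure

_GENERATION = 0
_SERVICE_END = 1


class SimTimeoutError(RuntimeError):
    """Simulation guard time exceeded before the completion target was met."""

    def __init__(self, message: str, partial: "SimResult"):
        super().__init__(message)
        self.partial = partial


@dataclass
class Signal:
    """One message or packet in transit."""

    __slots__ = ("signal_id", "set_id", "packet_index", "n_packets", "source",
                 "destination", "created_at", "hops", "path")

    signal_id: int
    set_id: int
    packet_index: int
    n_packets: int
    source: int
    destination: int
    created_at: float
    hops: int
    path: list | None


class _Node:
    """Server + LIFO/FIFO buffer state with time-integral accumulators."""

    __slots__ = ("server", "buffer", "last_t", "busy_time", "contents_time",
                 "arrivals", "ejections")

    def __init__(self) -> None:
        self.server: Signal | None = None
        self.buffer: deque = deque()  # newest at the left, oldest at the right
        self.last_t = 0.0
        self.busy_time = 0.0
        self.contents_time = 0.0
        self.arrivals = 0
        self.ejections = 0

    def touch(self, t: float) -> None:
        dt = t - self.last_t
        if dt > 0.0:
            occ = len(self.buffer)
            if self.server is not None:
                self.busy_time += dt
                occ += 1
            if occ:
                self.contents_time += occ * dt
            self.last_t = t


@dataclass(frozen=True)
class SimConfig:
    """All parameters of one simulation run.

    ``lam`` is the network-wide Poisson generation rate of messages (packet
    sets); ``mu`` the per-node service rate for a whole message; ``H`` the
    message buffer capacity in slots (None = unlimited). Under packet
    switching each message is split into ``n`` packets served at rate n*mu
    with capacity n*H. ``overtaking='follow-forerunner'`` makes packets 1..
    n-1 of a set replay the recorded path of packet 0 (sensible only with
    FIFO queueing, where the forerunner stays ahead).
    """

    strategy: StrategySpec
    switching: Literal["message", "packet"] = "message"
    lam: float = 0.01
    mu: float = 0.02
    H: int | None = 20
    n: int = 5
    queue_discipline: Literal["LIFO", "FIFO"] = "LIFO"
    overtaking: Literal["free", "follow-forerunner"] = "free"
    target_completions: int = 100
    max_sim_time: float = 1e7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.mu <= 0:
            raise ValueError("lam and mu must be positive")
        if self.n < 1 or self.target_completions < 1:
            raise ValueError("n and target_completions must be >= 1")
        if self.H is not None and self.H < 1:
            raise ValueError("H must be >= 1 or None for unlimited")
        if self.switching not in ("message", "packet"):
            raise ValueError(f"unknown switching architecture {self.switching!r}")
        if self.overtaking == "follow-forerunner" and self.queue_discipline != "FIFO":
            raise ValueError("follow-forerunner mode requires FIFO queueing")

    @property
    def signals_per_set(self) -> int:
        return self.n if self.switching == "packet" else 1

    @property
    def service_rate(self) -> float:
        return self.mu * self.signals_per_set

    @property
    def capacity_slots(self) -> int | None:
        return None if self.H is None else self.H * self.signals_per_set


@dataclass
class SimResult:
    """Outcome of one run: completion time, counts and per-node integrals."""

    config: SimConfig
    completion_time: float
    busy_time: np.ndarray
    contents_time: np.ndarray
    arrivals: np.ndarray
    ejections: np.ndarray
    generated: int
    delivered: int
    dropped: int
    residual: int
    completed_sets: int
    delivered_hops: np.ndarray
    delivered_latency: np.ndarray
    delivered_source: np.ndarray
    delivered_dest: np.ndarray
    delivered_set: np.ndarray
    delivered_packet_index: np.ndarray
    timed_out: bool = False
    paths: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.busy_time.shape[0]


def load_sim_config(path) -> SimConfig:
    """Read a SimConfig from a YAML or JSON file. The strategy is given as
    ``strategy: {kind: ..., c: ...}``; all other keys mirror SimConfig."""
    import json
    from pathlib import Path

    import yaml

    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    strat = data.pop("strategy")
    spec = StrategySpec(strat["kind"], strat.get("c"))
    return SimConfig(strategy=spec, **data)


def save_sim_config(config: SimConfig, path) -> None:
    """Write a SimConfig as YAML (or JSON for a .json path)."""
    import dataclasses
    import json
    from pathlib import Path

    import yaml

    data = dataclasses.asdict(config)
    data["strategy"] = {"kind": config.strategy.kind, "c": config.strategy.c}
    text = (json.dumps(data, indent=2) if str(path).endswith(".json")
            else yaml.safe_dump(data, sort_keys=False))
    Path(path).write_text(text)


def simulate(net: DirectedNetwork, config: SimConfig,
             ds: DistanceStructure | None = None,
             trace_paths: bool = False) -> SimResult:
    """Run one discrete-event simulation to ``target_completions`` deliveries.

    ``ds`` may be passed to reuse a prebuilt distance structure across runs
    (it is read-only apart from memoized next-hop tables). ``trace_paths``
    records every signal's node sequence in ``SimResult.paths``.
    """
    if ds is None:
        ds = build_distance_structure(net)
    n_nodes = net.n_nodes
    rng = np.random.default_rng(config.seed)
    router = Router(config.strategy, ds)
    k = config.signals_per_set
    rate = config.service_rate
    cap = config.capacity_slots
    lifo = config.queue_discipline == "LIFO"
    follow = config.overtaking == "follow-forerunner"
    trace = trace_paths or follow

    nodes = [_Node() for _ in range(n_nodes)]
    heap: list = []
    seq = 0  # stable tie-break for simultaneous events

    set_delivered: dict[int, int] = {}
    set_orphaned: set[int] = set()
    forerunner_path: dict[int, list] = {}
    paths: dict[tuple[int, int], list] = {}
    delivered_hops: list[int] = []
    delivered_latency: list[float] = []
    delivered_meta: list[tuple[int, int, int, int]] = []  # (source, dest, set, packet)

    generated = delivered = dropped = 0
    completed_sets = 0
    next_set_id = 0
    next_signal_id = 0
    t_first_gen = -1.0

    def start_service(node: _Node, node_idx: int, sig: Signal, t: float) -> None:
        nonlocal seq
        node.server = sig
        seq += 1
        heapq.heappush(heap, (t + rng.exponential(1.0 / rate), seq, _SERVICE_END, node_idx))

    def arrive(sig: Signal, node_idx: int, t: float) -> None:
        nonlocal dropped
        node = nodes[node_idx]
        node.touch(t)
        node.arrivals += 1
        if node.server is None:
            start_service(node, node_idx, sig, t)
            return
        node.buffer.appendleft(sig)
        if cap is not None and len(node.buffer) > cap:
            oldest = node.buffer.pop()
            node.ejections += 1
            dropped += 1
            set_orphaned.add(oldest.set_id)

    # first generation
    t0 = rng.exponential(1.0 / config.lam)
    heapq.heappush(heap, (t0, seq, _GENERATION, -1))

    t = t0
    while heap:
        t, _, kind, node_idx = heapq.heappop(heap)
        if t > config.max_sim_time:
            break

        if kind == _GENERATION:
            if t_first_gen < 0:
                t_first_gen = t
            source = int(rng.integers(n_nodes))
            dest = int(rng.integers(n_nodes - 1))
            if dest >= source:
                dest += 1
            set_id = next_set_id
            next_set_id += 1
            generated += k
            set_delivered[set_id] = 0
            for p_idx in range(k):
                sig = Signal(next_signal_id, set_id, p_idx, k, source, dest, t, 0,
                             [source] if trace else None)
                next_signal_id += 1
                if trace:
                    paths[(set_id, p_idx)] = sig.path
                    if p_idx == 0:
                        forerunner_path[set_id] = sig.path
                arrive(sig, source, t)
            seq += 1
            heapq.heappush(heap, (t + rng.exponential(1.0 / config.lam), seq, _GENERATION, -1))
            continue

        # service completion
        node = nodes[node_idx]
        sig = node.server
        node.touch(t)

        # routing decision (forerunner replay short-circuits the strategy)
        nxt = None
        if follow and sig.packet_index > 0:
            fpath = forerunner_path.get(sig.set_id)
            if fpath is not None and sig.hops + 1 < len(fpath):
                nxt = fpath[sig.hops + 1]
        if nxt is None:
            nxt = router.choose(sig.destination, node_idx, nodes, rng)
        sig.hops += 1
        if sig.path is not None:
            sig.path.append(nxt)

        if nxt == sig.destination:
            delivered += 1
            delivered_hops.append(sig.hops)
            delivered_latency.append(t - sig.created_at)
            delivered_meta.append((sig.source, sig.destination, sig.set_id, sig.packet_index))
            got = set_delivered[sig.set_id] + 1
            set_delivered[sig.set_id] = got
            if got == k:
                completed_sets += 1
                if completed_sets >= config.target_completions:
                    node.server = None
                    break
        else:
            arrive(sig, nxt, t)

        node.server = None
        if node.buffer:
            pulled = node.buffer.popleft() if lifo else node.buffer.pop()
            start_service(node, node_idx, pulled, t)

    timed_out = completed_sets < config.target_completions
    for node in nodes:
        node.touch(t)

    residual = sum((node.server is not None) + len(node.buffer) for node in nodes)
    result = SimResult(
        config=config,
        completion_time=t - t_first_gen if t_first_gen >= 0 else 0.0,
        busy_time=np.array([node.busy_time for node in nodes]),
        contents_time=np.array([node.contents_time for node in nodes]),
        arrivals=np.array([node.arrivals for node in nodes], dtype=np.int64),
        ejections=np.array([node.ejections for node in nodes], dtype=np.int64),
        generated=generated,
        delivered=delivered,
        dropped=dropped,
        residual=residual,
        completed_sets=completed_sets,
        delivered_hops=np.asarray(delivered_hops, dtype=np.int64),
        delivered_latency=np.asarray(delivered_latency),
        delivered_source=np.array([m[0] for m in delivered_meta], dtype=np.int64),
        delivered_dest=np.array([m[1] for m in delivered_meta], dtype=np.int64),
        delivered_set=np.array([m[2] for m in delivered_meta], dtype=np.int64),
        delivered_packet_index=np.array([m[3] for m in delivered_meta], dtype=np.int64),
        timed_out=timed_out,
        paths=paths if trace_paths else {},
    )
    if timed_out:
        raise SimTimeoutError(
            f"only {completed_sets}/{config.target_completions} sets completed "
            f"by the guard time {config.max_sim_time:g}", result)
    return result


def run_batch(net: DirectedNetwork, config: SimConfig, n_runs: int,
              seed_base: int, ds: DistanceStructure | None = None) -> list[SimResult]:
    """``n_runs`` independent seeded runs; run i uses a child seed of
    ``seed_base`` so the batch is reproducible and order-stable.

    Runs that hit the simulation guard time are kept in the list as their
    partial results (flagged ``timed_out``) rather than aborting the batch.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if ds is None:
        ds = build_distance_structure(net)
    seeds = np.random.SeedSequence(seed_base).generate_state(n_runs) % (2**31)
    results = []
    for s in seeds:
        cfg = _with_seed(config, int(s))
        try:
            results.append(simulate(net, cfg, ds=ds))
        except SimTimeoutError as exc:
            results.append(exc.partial)
    return results


def _with_seed(config: SimConfig, seed: int) -> SimConfig:
    from dataclasses import replace
    return replace(config, seed=seed)


# ---------------------------------------------------------------------------
# communication metrics

def utilization(result: SimResult, node: int | None = None) -> float | np.ndarray:
    """Proportion of the run a node's server was busy, in [0, 1]."""
    u = result.busy_time / result.completion_time
    return u if node is None else float(u[node])


def normalized_node_contents(result: SimResult, node: int | None = None) -> float | np.ndarray:
    """Time-averaged node contents n_i(t) = s_i(t) + q_i(t), normalized by
    its maximum 1 + H (messages) or 1 + nH (packets). NaN with unlimited
    buffers, where no finite maximum exists."""
    cap = result.config.capacity_slots
    denom = np.nan if cap is None else (1.0 + cap)
    v = result.contents_time / result.completion_time / denom
    return v if node is None else float(v[node])


def blocking_probability(result: SimResult, node: int | None = None) -> float | np.ndarray:
    """Fraction of arrivals at a node that ejected a buffered signal
    (0 where the node saw no arrivals)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(result.arrivals > 0, result.ejections / result.arrivals, 0.0)
    return b if node is None else float(b[node])


def ratio_r(results: list[SimResult]) -> float:
    """Ratio r of mean utilization to mean normalized node contents, the
    means taken over nodes and runs. Larger r means traffic is spread over
    many busy-but-uncongested nodes rather than piled into few buffers."""
    u = float(np.mean([utilization(res) for res in results]))
    q = float(np.mean([normalized_node_contents(res) for res in results]))
    if q == 0:
        raise ZeroDivisionError("mean normalized node contents is zero")
    return u / q
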