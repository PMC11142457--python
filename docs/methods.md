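# Methods

## The model

`conncomm` simulates the propagation of discrete signals on a directed
structural brain network with a discrete-event queueing model. Every node is
a single server with a bounded buffer; every signal is either a whole
*message* or one of the *n* equally sized *packets* a message is split into.
The two switching architectures differ only in that split: packet switching
divides each message into n independently routed packets, served n times
faster (rate nμ instead of μ) and buffered in n times as many slots (nH
instead of H), so the total work and storage per message are identical.

Mechanics of one run:

1. **Generation.** Message (or packet-set) generations form one
   network-wide Poisson process of rate λ. Each generation draws a uniform
   source node, a uniform destination among the remaining nodes, and
   injects 1 message or n simultaneous packets at the source (in packet
   order). Injected signals are serviced at their source before the first
   hop.
2. **Queueing.** An arriving signal enters the idle server or the buffer
   front. Service times are exponential. The buffer is LIFO (newest served
   first — modelling the temporal decay of biological signals); a signal
   arriving at a full buffer ejects the *oldest* buffered signal, which is
   dropped. FIFO is available as a variant.
3. **Routing.** On service completion the signal picks a next hop under its
   propagation strategy and is transmitted instantaneously (no link
   delays). Arrival at the destination removes the signal immediately,
   without service and without occupying a slot.
4. **Completion.** The run ends when a target number of messages / complete
   packet sets (all n packets) have been delivered; the reported completion
   time is the span from the first generation to that instant. Sets
   orphaned by a dropped packet never complete; generation simply continues
   until enough intact sets make it. A guard time bounds runaway runs and
   raises a timeout carrying partial results.

All randomness in a run comes from one seeded generator with a fixed draw
order (interarrival, source, destination at generations; routing then
service-time draws at completions), so every run, batch and experiment
table is bit-reproducible from its seed. Message switching is implemented
as the n = 1 case of packet switching, making the two architectures
trajectory-identical at n = 1 by construction (and by test).

## Propagation strategies

With binary edges all distances are d = 1; with weighted edges, weights are
first mapped affinely into (0, 1) and d = log(1/w) > 0. Geodesics g come
from Dijkstra on those distances. We take log(1/w), not −log(1/w): the
latter is negative on (0, 1) and cannot serve as a path length.

- **RW** — uniform over out-neighbors (binary) or weight-proportional
  (weighted). No knowledge of the network.
- **SP** — uniform over the out-neighbors on a shortest path to the
  destination (j qualifies iff d_ij + g_jD = g_iD). Needs global topology.
- **iRW_d** — destination if adjacent, else RW.
- **iRW_a** — prefer out-neighbors with an idle server; if none, those with
  the shortest buffer queue (queue only — the first clause already keys on
  the server). Ties resolved in the manner of RW (uniform on binary,
  weight-proportional on weighted networks). Occupancy is read at the
  instant of the routing decision, with no staleness.
- **iRW_a+d** — the direct rule first, then the avoidance rule.
- **bRW** — p(i→j|D) ∝ exp(−(c(d_ij + g_jD) + d_ij)), normalized over
  out-neighbors. c = 0 reduces exactly to RW; c → ∞ concentrates on the SP
  next-hop set (ties shared as in SP). The maximum exponent is subtracted
  before exponentiation, which leaves probabilities invariant and avoids
  underflow at large c; transition vectors sum to 1 to 1e-12 by test.

Defaults follow the queueing regime of the sparse-connectome literature:
λ = 0.01 generations per time unit, μ = 0.02, H = 20 buffer slots, n = 5
packets per message, 100 completed transmissions per run. λ/μ governs the
load; the sensitivity suite re-runs experiments at n ∈ {3, 10}, unlimited
H, and halved/doubled λ at fixed μ.

## Statistics

Per condition, packet and message completion-time samples are compared with
a two-sided Mann-Whitney U test (midranks; exact for tiny tie-free samples,
tie-corrected normal approximation otherwise), corrected across the
condition family (one experiment panel — e.g. five strategies, or the 28
values of a c sweep; never pooled across panels) by Benjamini-Hochberg FDR,
and summarized by Cliff's delta with the convention delta > 0 = packet
slower. Delta and the BH step-up are cross-checked against brute-force
enumeration in tests; the U test's type-I rate is checked at ~0.05 under
the null.

Bottleneck nodes are flagged where packet-mode mean normalized node
contents exceed 1.5x the message-mode value. The diversity ratio r is the
mean (over nodes and runs) utilization divided by the mean normalized node
contents; r_packet / r_message measures how much packetization spreads load
across the network.

## Synthetic fixtures

The generators produce networks with the statistical structure the analyses
assume, not copies of any empirical connectome:

- **Hub network** (default 242 nodes, 4,090 edges, density 0.070): a random
  Hamiltonian cycle guarantees strong connectivity; remaining edges draw
  their targets with weight 1 + boost (default 7:1) for 10 designated hubs,
  putting hub in-degrees ~5-6x the median — the sparse-connectome regime in
  which a few integrator regions dominate in-degree. With boost 0 the
  in-degree distribution is indistinguishable from a fully randomized
  surrogate's (KS test).
- **Dense weighted network** (default 213 nodes, density 0.373): uniform
  edge placement (binarized in-degree tightly binomial, minimum a large
  fraction of N, geodesics concentrated on lengths 1-2) with log-normal
  weights, hub columns multiplied by 6 — hubs visible in in-strength only,
  as in dense tracer-strength data.
- **Toy transition graph**: 5 nodes; the current node has three
  out-neighbors at geodesic distances 1, 2, 3 from the destination, the
  minimal setting in which the bRW bias is visible across c.

What the fixtures do not emulate: the real connectomes' spatial embedding,
community structure, reciprocity and exact degree sequences. Tests passing
on fixtures therefore establish that the *mechanism* (hub congestion under
packetized slow strategies; relief under balanced ones) behaves as
described, not that any specific empirical delta is reproduced.

## Surrogates

Fully randomized surrogates redraw all E edges uniformly over off-diagonal
ordered pairs (weights reassigned as a multiset). Degree-preserving
surrogates apply 10·E accepted double-edge swaps (a→b, c→d) ⇒ (a→d, c→b),
rejecting self-loops and duplicates; each edge keeps its weight, so the
weight multiset survives but in/out-strength do not (the degree-preserving
null is primarily a binary-network tool). Both regenerate until strongly
connected (bounded retries). A surrogate batch is generated once from a
master seed and reused across every strategy x switching condition.

## Problem sizes and numerical choices

Full-scale batches (100 runs x 100 completions per condition and
architecture) are expensive under congested packet-mode RW, where most
packet sets lose a member at a hub and generation must continue until 100
intact sets complete. The shipped analysis drivers, tests and the
acceptance script therefore run reduced designs — typically 12-20 runs x 60
completions on the full-size fixtures, and a 121-node fixture for the
100-pair sign test — chosen so the direction pattern and effect magnitudes
are stable while a single-CPU rerun of the whole suite stays within
minutes. Cliff's delta at 20 runs per arm is granular (steps of 1/400);
complete separation (|delta| = 1) is unaffected.

Other numerical choices: weighted normalization keeps endpoints at
delta = 1e-6 and 1 − delta so log-distances are finite; geodesic/next-hop
comparisons use a 1e-9 tolerance on weighted paths; simultaneous events are
ordered by (time, insertion sequence); per-run seeds derive from a master
seed via `numpy.random.SeedSequence` with message- and packet-mode batches
on disjoint streams (independent batches, as in separately repeated
experiments).

## No-overtaking variant

Packet reassembly order is a modelling concern: with free routing, packets
of one message can overtake each other. The `follow-forerunner` mode
answers it: FIFO queueing plus packets 1..n−1 replaying the recorded path
of packet 0. Under FIFO the forerunner reaches and clears every node on the
path before its followers, so deliveries within a set occur in emission
order — asserted on traced paths in tests. If the forerunner is dropped the
set is already orphaned and followers fall back to the strategy.

## Known limitations

- No link delays, node heterogeneity or spatial geometry; no
  community-preserving or geometry-preserving surrogates.
- Navigation and broadcasting strategies are out of scope, as is circuit
  switching (incompatible with hop-by-hop strategies).
- Metrics integrate over the whole run with no warm-up discard, matching
  the finite-run design they are reported for; they are not steady-state
  estimates.
- The blocking probability is per-arrival at each node; with unlimited
  buffers it is identically 0 and normalized node contents are undefined
  (reported as NaN).
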