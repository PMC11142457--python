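#!/usr/bin/env python
"""Surrogate-network analysis: is it the hubs, or the whole topology?

Rewires the hub network two ways — fully randomized (hubs destroyed) and
degree-preserving (hubs kept) — and reruns the RW switching comparison on a
batch of surrogates. Expected: with hubs destroyed, packetization *shortens*
RW completion times; with degrees preserved, packet switching stays slower,
implicating high in-degree hubs (and residual topology) as the bottleneck
mechanism. The same surrogate batch is reused across both switching
architectures.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from conncomm import (SimConfig, StrategySpec, build_distance_structure,
                      cliffs_delta, degree_summary, generate_hub_network,
                      mann_whitney_u, simulate, surrogate_batch)

OUT = Path(__file__).resolve().parent.parent / "results" / "surrogates"
SEED = 1
N_SURROGATES = 12  # one run per surrogate realization per architecture


def compare_on(surrogates, label):
    samples = {}
    for sw in ("message", "packet"):
        times = []
        for i, net in enumerate(surrogates):
            cfg = SimConfig(strategy=StrategySpec("RW"), switching=sw,
                            target_completions=60, seed=SEED + 1000 * (sw == "packet") + i)
            times.append(simulate(net, cfg).completion_time)
        samples[sw] = np.asarray(times)
    delta = cliffs_delta(samples["packet"], samples["message"])
    _, p = mann_whitney_u(samples["packet"], samples["message"])
    print(f"{label}: RW Cliff's delta (packet vs message) = {delta:+.3f}, p = {p:.3g}")
    return {"condition": label, "delta": delta, "p": p,
            "median_message": float(np.median(samples["message"])),
            "median_packet": float(np.median(samples["packet"]))}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    net = generate_hub_network(seed=SEED)
    deg = degree_summary(net).in_degree

    full = surrogate_batch(net, "full", n_surrogates=N_SURROGATES, master_seed=SEED)
    deg_pres = surrogate_batch(net, "degree", n_surrogates=N_SURROGATES, master_seed=SEED)
    fdeg = degree_summary(full[0]).in_degree
    print(f"original max in-degree {deg.max()} -> fully randomized {fdeg.max()} "
          f"(hubs destroyed); degree-preserved keeps the sequence exactly: "
          f"{bool((degree_summary(deg_pres[0]).in_degree == deg).all())}")

    rows = [compare_on(full, "fully_randomized"),
            compare_on(deg_pres, "degree_preserved")]
    pd.DataFrame(rows).to_csv(OUT / "surrogate_rw_comparison.csv", index=False)
    print(f"\ntables written to {OUT}")


if __name__ == "__main__":
    main()
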