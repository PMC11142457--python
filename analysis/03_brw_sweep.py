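#!/usr/bin/env python
"""Biased-random-walk sweep: the effect of packetization across c.

Sweeps the bRW bias parameter c over a subgrid of the 28-value grid
(0.01 ... 10) and compares message vs packet completion times at each c,
FDR-corrected within the sweep family. Expected: packet-slower at small c
(RW-like), packet-faster at intermediate c, no difference at large c
(SP-like). A full-grid sweep is a matter of swapping in BRW_C_GRID.
"""

from pathlib import Path

from conncomm import SimConfig, StrategySpec, generate_hub_network, run_experiment

OUT = Path(__file__).resolve().parent.parent / "results" / "brw_sweep"
SEED = 1
C_VALUES = (0.01, 0.1, 0.5, 1.0, 2.0, 10.0)


def main() -> None:
    net = generate_hub_network(seed=SEED)
    specs = [StrategySpec("bRW", c) for c in C_VALUES]
    base = SimConfig(strategy=specs[0], target_completions=60)
    bundle = run_experiment(net, specs, base, n_runs=15, master_seed=SEED + 10)
    bundle.save(OUT)
    print(bundle.comparison.table.to_string(index=False))
    print(f"\ntables written to {OUT}")


if __name__ == "__main__":
    main()
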