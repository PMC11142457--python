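"""End-to-end experiments: batches per (strategy x switching architecture),
completion-time comparison, nodewise metrics, bottleneck identification and
tidy report tables.

One master seed drives everything: per (condition, architecture) the seed
splitter hands out disjoint child streams, so message- and packet-mode
batches are independent (as in separately repeated experiments) yet the
whole report reproduces bit-identically from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .des_engine import (SimConfig, SimResult, blocking_probability,
                         normalized_node_contents, ratio_r, run_batch, utilization)
from .network_model import DirectedNetwork
from .routing_strategies import StrategySpec, build_distance_structure
from .stats_compare import ComparisonResult, compare_architectures

BOTTLENECK_FACTOR = 1.5  # packet-mode contents > 1.5x message-mode flags a node


@dataclass
class ExperimentBundle:
    """All tables of one experiment panel."""

    completion_times: pd.DataFrame   # run, condition, switching, completion_time, timed_out
    comparison: ComparisonResult     # per condition: U, p, p_adj, delta, direction
    node_metrics: pd.DataFrame       # node, condition, switching, utilization, ...
    r_table: pd.DataFrame            # condition, r_message, r_packet, r_ratio
    bottlenecks: dict[str, list[str]]
    quantiles: pd.DataFrame

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.completion_times.to_csv(outdir / "completion_times.csv", index=False)
        self.comparison.to_csv(outdir / "comparison.csv")
        self.node_metrics.to_csv(outdir / "node_metrics.csv", index=False)
        self.r_table.to_csv(outdir / "r_table.csv", index=False)
        self.quantiles.to_csv(outdir / "completion_time_quantiles.csv", index=False)
        pd.Series({k: ";".join(v) for k, v in self.bottlenecks.items()}, name="bottlenecks") \
            .rename_axis("condition").to_csv(outdir / "bottlenecks.csv")


def _seed_base(master_seed: int, cond_idx: int, arch_idx: int) -> int:
    child = np.random.SeedSequence(master_seed).spawn(2 * cond_idx + arch_idx + 1)[-1]
    return int(child.generate_state(1)[0] % (2**31))


def run_experiment(
    net: DirectedNetwork,
    strategies: list[StrategySpec],
    base_config: SimConfig | None = None,
    n_runs: int = 100,
    master_seed: int = 0,
) -> ExperimentBundle:
    """Run message- and packet-switching batches for every strategy and
    assemble the comparison tables (FDR-corrected within this panel's family
    of conditions)."""
    if base_config is None:
        base_config = SimConfig(strategy=strategies[0])
    # weighted nets must arrive normalized into (0, 1); build once, share across runs
    ds = build_distance_structure(net)
    ct_rows, metric_rows, r_rows = [], [], []
    msg_samples: dict[str, np.ndarray] = {}
    pkt_samples: dict[str, np.ndarray] = {}
    contents_mean: dict[tuple[str, str], np.ndarray] = {}
    bottlenecks: dict[str, list[str]] = {}

    for ci, spec in enumerate(strategies):
        label = spec.label
        for ai, switching in enumerate(("message", "packet")):
            cfg = replace(base_config, strategy=spec, switching=switching)
            batch = run_batch(net, cfg, n_runs, _seed_base(master_seed, ci, ai), ds=ds)
            times = np.array([b.completion_time for b in batch])
            (msg_samples if switching == "message" else pkt_samples)[label] = times
            for run, b in enumerate(batch):
                ct_rows.append({"run": run, "condition": label, "switching": switching,
                                "completion_time": b.completion_time,
                                "dropped": b.dropped, "timed_out": b.timed_out})
            util = np.mean([utilization(b) for b in batch], axis=0)
            contents = np.mean([normalized_node_contents(b) for b in batch], axis=0)
            block = np.mean([blocking_probability(b) for b in batch], axis=0)
            contents_mean[(label, switching)] = contents
            for node in range(net.n_nodes):
                metric_rows.append({
                    "node": net.labels[node], "condition": label, "switching": switching,
                    "utilization": util[node], "normalized_node_contents": contents[node],
                    "blocking_probability": block[node],
                })
            r_rows.append({"condition": label, "switching": switching,
                           "r": _safe_ratio_r(batch)})
        pkt_c, msg_c = contents_mean[(label, "packet")], contents_mean[(label, "message")]
        flagged = np.flatnonzero((msg_c > 0) & (pkt_c > BOTTLENECK_FACTOR * msg_c))
        bottlenecks[label] = [net.labels[i] for i in flagged]

    comparison = compare_architectures(msg_samples, pkt_samples)
    ct = pd.DataFrame(ct_rows)
    r_wide = pd.DataFrame(r_rows).pivot(index="condition", columns="switching", values="r")
    r_table = pd.DataFrame({
        "condition": r_wide.index,
        "r_message": r_wide["message"].to_numpy(),
        "r_packet": r_wide["packet"].to_numpy(),
    })
    r_table["r_ratio"] = r_table["r_packet"] / r_table["r_message"]
    quantiles = (
        ct.groupby(["condition", "switching"])["completion_time"]
        .quantile([0.0, 0.25, 0.5, 0.75, 1.0]).unstack()
        .rename(columns={0.0: "min", 0.25: "q25", 0.5: "median", 0.75: "q75", 1.0: "max"})
        .reset_index()
    )
    return ExperimentBundle(ct, comparison, pd.DataFrame(metric_rows), r_table,
                            bottlenecks, quantiles)


def _safe_ratio_r(batch: list[SimResult]) -> float:
    try:
        return ratio_r(batch)
    except ZeroDivisionError:
        return np.nan


def sensitivity_suite(
    net: DirectedNetwork,
    strategies: list[StrategySpec],
    base_config: SimConfig,
    n_runs: int = 100,
    master_seed: int = 0,
    variants: dict[str, dict] | None = None,
) -> dict[str, ExperimentBundle]:
    """Re-run an experiment under parameter variants with identical schema.

    The default variants vary the packets-per-message count n (service rate
    and buffer capacity scale with it), lift the buffer limit, and halve /
    double the generation rate lam at fixed mu.
    """
    if variants is None:
        variants = {
            "n3": {"n": 3},
            "n10": {"n": 10},
            "unlimited_H": {"H": None},
            "lam_half": {"lam": base_config.lam / 2},
            "lam_double": {"lam": base_config.lam * 2},
        }
    bundles = {}
    for name, overrides in variants.items():
        cfg = replace(base_config, **overrides)
        bundles[name] = run_experiment(net, strategies, cfg, n_runs=n_runs,
                                       master_seed=master_seed)
    return bundles
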