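"""Nonparametric comparison of message- vs packet-switching completion times.

Each experimental condition (a strategy, or one c value of a biased-random-
walk sweep) yields two samples of transmission completion times. They are
compared with a two-sided Mann-Whitney U test, corrected across the
condition family by Benjamini-Hochberg FDR, and summarized by Cliff's delta.

Sign convention: delta = P(packet > message) - P(packet < message) over all
sample pairs, so positive delta means packet switching is *slower* and
delta = +1/-1 complete separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05


def mann_whitney_u(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    Midranks handle ties; scipy picks exact enumeration for small tie-free
    samples and the tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, position-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cliffs_delta(x, y) -> float:
    """Cliff's delta: (#{x_i > y_j} - #{x_i < y_j}) / (|x| |y|), in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    diff = x[:, None] - y[None, :]
    return float((np.count_nonzero(diff > 0) - np.count_nonzero(diff < 0)) / diff.size)


@dataclass(frozen=True)
class ComparisonResult:
    """Per-condition U / p / adjusted p / Cliff's delta table."""

    table: pd.DataFrame  # condition, U, p, p_adj, delta, direction

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=2)


def compare_architectures(
    message_batches: dict[str, np.ndarray] | list,
    packet_batches: dict[str, np.ndarray] | list,
    conditions: list[str] | None = None,
    alpha: float = ALPHA,
) -> ComparisonResult:
    """Compare completion-time samples per condition, FDR-corrected within
    the given family of conditions (never pooled across experiment panels).

    Inputs are dicts keyed by condition label (or parallel lists plus
    ``conditions``). Direction labels at adjusted p < alpha follow the sign
    of Cliff's delta: positive = packet-slower.
    """
    if isinstance(message_batches, dict):
        conditions = list(message_batches)
        msg = [np.asarray(message_batches[c], dtype=float) for c in conditions]
        pkt = [np.asarray(packet_batches[c], dtype=float) for c in conditions]
    else:
        if conditions is None or len(conditions) != len(message_batches):
            raise ValueError("conditions must match the number of sample pairs")
        msg = [np.asarray(v, dtype=float) for v in message_batches]
        pkt = [np.asarray(v, dtype=float) for v in packet_batches]
    if len(msg) != len(pkt):
        raise ValueError("message and packet families differ in length")

    rows = []
    for cond, m, p in zip(conditions, msg, pkt):
        u, pval = mann_whitney_u(p, m)
        rows.append({"condition": cond, "U": u, "p": pval, "delta": cliffs_delta(p, m)})
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_fdr(df["p"].to_numpy())
    df["direction"] = [
        "no-difference" if padj >= alpha else ("packet-slower" if d > 0 else "packet-faster")
        for padj, d in zip(df["p_adj"], df["delta"])
    ]
    return ComparisonResult(df[["condition", "U", "p", "p_adj", "delta", "direction"]])
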