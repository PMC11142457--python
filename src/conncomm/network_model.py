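"""Directed structural brain networks: loading, validation, normalization.

The adjacency convention throughout is row = source, column = target:
``weights[i, j]`` is the weight of the directed edge i -> j, matching the
tracer-matrix convention ("connection from i to j"). Self-connections are
forbidden. Weighted networks are mapped affinely into (0, 1) before use in
simulation so that log-distances ``log(1/w)`` are finite and positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


class NetworkFormatError(ValueError):
    """Raised when an adjacency matrix violates the network invariants."""


@dataclass(frozen=True)
class DirectedNetwork:
    """A node-labelled directed graph with nonnegative edge weights.

    Parameters
    ----------
    weights
        n x n nonnegative matrix; entry (i, j) is the weight of edge i -> j.
    labels
        Ordered node names; defaults to stringified indices.
    """

    weights: np.ndarray
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise NetworkFormatError(f"adjacency matrix must be square, got {w.shape}")
        if np.any(w < 0):
            raise NetworkFormatError("negative edge weights are not allowed")
        if np.any(np.diag(w) != 0):
            bad = int(np.flatnonzero(np.diag(w))[0])
            raise NetworkFormatError(
                f"nonzero diagonal entry at node {bad}: self-connections are not allowed"
            )
        if not np.all(np.isfinite(w)):
            raise NetworkFormatError("non-finite entries in adjacency matrix")
        object.__setattr__(self, "weights", w)
        if not self.labels:
            object.__setattr__(self, "labels", tuple(str(i) for i in range(w.shape[0])))
        elif len(self.labels) != w.shape[0]:
            raise NetworkFormatError("label count does not match matrix size")
        else:
            object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of nonzero off-diagonal entries (directed edges)."""
        return int(np.count_nonzero(self.weights))

    @property
    def is_binary(self) -> bool:
        w = self.weights
        return bool(np.all((w == 0) | (w == 1)))

    @property
    def density(self) -> float:
        """Edge density E / (N * (N - 1))."""
        n = self.n_nodes
        return self.n_edges / (n * (n - 1))

    def is_strongly_connected(self) -> bool:
        n_comp, _ = connected_components(
            csr_matrix(self.weights != 0), directed=True, connection="strong"
        )
        return n_comp == 1

    def require_strongly_connected(self) -> None:
        if not self.is_strongly_connected():
            raise NetworkFormatError(
                "network is not strongly connected; some destinations are unreachable"
            )


def load_adjacency(
    path: str | Path,
    format: str | None = None,
    *,
    sheet: str | int = 0,
) -> DirectedNetwork:
    """Read a square adjacency matrix from CSV, TSV or an XLSX sheet.

    A header row plus first label column is detected when the first cell of
    the file does not parse as a number; labels are then taken from the
    header. A nonzero diagonal is an error, never silently dropped.
    """
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".xlsx": "xlsx"}.get(path.suffix.lower(), "csv")
    if format == "xlsx":
        raw = pd.read_excel(path, sheet_name=sheet, header=None)
    else:
        sep = "\t" if format == "tsv" else ","
        raw = pd.read_csv(path, sep=sep, header=None)

    first = raw.iat[0, 0]
    # a labelled matrix has a non-numeric (or empty index-name) corner cell
    has_header = (isinstance(first, str) and not _is_number(first)) or (
        isinstance(first, float) and np.isnan(first))
    if has_header:
        labels = tuple(str(x) for x in raw.iloc[0, 1:])
        body = raw.iloc[1:, 1:]
    else:
        labels = ()
        body = raw
    try:
        w = body.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise NetworkFormatError(f"could not parse {path} as a numeric matrix: {exc}") from exc
    return DirectedNetwork(w, labels)


def save_adjacency(net: DirectedNetwork, path: str | Path, *, header: bool = True) -> None:
    """Write the adjacency matrix as CSV (integer cells for binary nets)."""
    path = Path(path)
    w = net.weights
    if net.is_binary:
        w = w.astype(int)
    df = pd.DataFrame(w, index=net.labels, columns=net.labels)
    df.to_csv(path, index=header, header=header)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def normalize_weights(net: DirectedNetwork, delta: float = 1e-6) -> DirectedNetwork:
    """Affinely map nonzero weights onto [delta, 1 - delta].

    w' = delta + (1 - 2 delta) (w - w_min) / (w_max - w_min), with the min and
    max taken over nonzero weights; zeros stay zero. Order-preserving. Keeping
    the endpoints off 0 and 1 keeps log-distances finite and strictly positive.
    """
    if not 0 < delta < 0.5:
        raise ValueError("delta must lie in (0, 0.5)")
    w = net.weights
    nz = w[w > 0]
    if nz.size == 0:
        raise NetworkFormatError("network has no edges")
    w_min, w_max = nz.min(), nz.max()
    if w_min == w_max:
        raise NetworkFormatError(
            "all nonzero weights are equal: the affine map onto (0, 1) is degenerate"
        )
    out = np.zeros_like(w)
    mask = w > 0
    out[mask] = delta + (1.0 - 2.0 * delta) * (w[mask] - w_min) / (w_max - w_min)
    return replace(net, weights=out)


def binarize(net: DirectedNetwork) -> DirectedNetwork:
    """Replace every nonzero weight with 1."""
    return replace(net, weights=(net.weights > 0).astype(float))


def degree_summary(net: DirectedNetwork) -> pd.DataFrame:
    """Tidy per-node degree/strength table.

    Columns: node, in_degree, out_degree, in_strength, out_strength.
    in_strength is the sum of incoming weights (column sums); for binary
    networks it coincides with in_degree.
    """
    w = net.weights
    adj = w > 0
    return pd.DataFrame(
        {
            "node": list(net.labels),
            "in_degree": adj.sum(axis=0).astype(int),
            "out_degree": adj.sum(axis=1).astype(int),
            "in_strength": w.sum(axis=0),
            "out_strength": w.sum(axis=1),
        }
    )
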