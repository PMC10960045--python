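"""Network containers, file I/O and structural property statistics.

The adjacency convention throughout the package follows the linear-dynamics
matrix A of ``x' = Ax + Bu``: entry ``adjacency[j, i] == 1`` encodes the
directed link ``i -> j``.  Connectome-style networks built from undirected
sources are stored with a symmetric adjacency (every undirected link becomes
two directed links), so the convention is invisible there but matters for
general digraphs.

Node indices are 0-based internally; labels, when present, carry the external
(e.g. atlas region) names and are used by the file readers/writers and CLI.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path


class NetworkFormatError(ValueError):
    """Raised when an input file violates the expected network format."""


def _check_labels(labels: Sequence[str] | None, n: int) -> list[str] | None:
    if labels is None:
        return None
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise NetworkFormatError(
            f"label list has length {len(labels)}, expected {n}")
    if len(set(labels)) != len(labels):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise NetworkFormatError(f"duplicate labels: {dup}")
    return labels


@dataclass
class WeightedNetwork:
    """A weighted directed network; ``weights[j, i]`` is the strength of i->j."""

    weights: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise NetworkFormatError(f"weight matrix must be square, got {w.shape}")
        if np.any(w < 0):
            bad = np.argwhere(w < 0)[0]
            raise NetworkFormatError(
                f"negative weight at row {bad[0]}, column {bad[1]}")
        self.weights = w
        self.labels = _check_labels(self.labels, w.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class BinaryDirectedNetwork:
    """A binary structural network; ``adjacency[j, i] == 1`` means link i->j."""

    adjacency: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise NetworkFormatError(f"adjacency must be square, got {a.shape}")
        if not np.isin(a, (0, 1)).all():
            raise NetworkFormatError("adjacency entries must be 0 or 1")
        self.adjacency = a.astype(np.int8)
        self.labels = _check_labels(self.labels, a.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_links(self) -> int:
        """Directed link count."""
        return int(self.adjacency.sum())

    @property
    def is_symmetric(self) -> bool:
        return bool(np.array_equal(self.adjacency, self.adjacency.T))

    @property
    def out_degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=0), dtype=int)

    @property
    def in_degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1), dtype=int)

    @property
    def degrees(self) -> np.ndarray:
        """Undirected degree for symmetric networks (== out == in there)."""
        return (self.out_degrees + self.in_degrees) // 2 \
            if self.is_symmetric else self.out_degrees + self.in_degrees

    def edges(self) -> list[tuple[int, int]]:
        """Directed links as (source, target) pairs."""
        tgt, src = np.nonzero(self.adjacency)
        return list(zip(src.tolist(), tgt.tolist()))

    def label_of(self, i: int) -> str:
        return self.labels[i] if self.labels is not None else str(i + 1)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges())
        return g


@dataclass
class NetworkProperties:
    """Structural summary statistics of a binary directed network."""

    n_nodes: int
    n_links: int
    isolated_nodes: list[str]
    heterogeneity: float
    mean_degree: float
    k_min: int
    k_max: int
    mean_distance: float


# ---------------------------------------------------------------------------
# File I/O

def _read_matrix_csv(path: Path) -> WeightedNetwork:
    raw = pd.read_csv(path, header=None, dtype=str)
    # a header of region labels makes the file one row taller than wide
    if raw.shape[0] == raw.shape[1] + 1:
        labels = [str(x) for x in raw.iloc[0]]
        body = raw.iloc[1:]
    else:
        labels = None
        body = raw
    try:
        mat = body.to_numpy(dtype=float)
    except ValueError as exc:
        raise NetworkFormatError(f"{path}: non-numeric entry ({exc})") from exc
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise NetworkFormatError(
            f"{path}: matrix is {mat.shape[0]}x{mat.shape[1]}, expected square")
    return WeightedNetwork(weights=mat, labels=labels)


def _read_edgelist(path: Path) -> WeightedNetwork:
    rows: list[tuple[str, str, float]] = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) not in (2, 3):
            raise NetworkFormatError(
                f"{path}:{ln}: expected source<TAB>target[<TAB>weight], got {line!r}")
        w = 1.0 if len(parts) == 2 else float(parts[2])
        if w < 0:
            raise NetworkFormatError(f"{path}:{ln}: negative weight {w}")
        rows.append((parts[0], parts[1], w))
    labels: list[str] = []
    for s, t, _ in rows:
        for name in (s, t):
            if name not in labels:
                labels.append(name)
    idx = {name: i for i, name in enumerate(labels)}
    n = len(labels)
    mat = np.zeros((n, n))
    for s, t, w in rows:
        mat[idx[t], idx[s]] = w  # i -> j stored at [j, i]
    return WeightedNetwork(weights=mat, labels=labels)


def read_network(path: str | Path, format: str | None = None) -> WeightedNetwork:
    """Read a network from ``matrix-csv`` (square CSV, optional label header)
    or ``edgelist`` (TSV ``source<TAB>target<TAB>weight``) format.

    The format is inferred from the extension (.csv vs .tsv/.txt) when not
    given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "matrix-csv" if path.suffix.lower() == ".csv" else "edgelist"
    if format == "matrix-csv":
        return _read_matrix_csv(path)
    if format == "edgelist":
        return _read_edgelist(path)
    raise ValueError(f"unknown format {format!r}")


def write_network(net: WeightedNetwork | BinaryDirectedNetwork,
                  path: str | Path, format: str | None = None) -> None:
    """Write a network in either supported format (see :func:`read_network`)."""
    path = Path(path)
    if format is None:
        format = "matrix-csv" if path.suffix.lower() == ".csv" else "edgelist"
    mat = net.weights if isinstance(net, WeightedNetwork) else net.adjacency
    labels = net.labels or [str(i + 1) for i in range(mat.shape[0])]
    if format == "matrix-csv":
        pd.DataFrame(np.asarray(mat, dtype=float), columns=labels).to_csv(
            path, index=False)
    elif format == "edgelist":
        lines = []
        tgt, src = np.nonzero(mat)
        for j, i in zip(tgt.tolist(), src.tolist()):
            lines.append(f"{labels[i]}\t{labels[j]}\t{mat[j, i]:g}")
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Construction operations

def binarize(net: WeightedNetwork) -> BinaryDirectedNetwork:
    """Threshold every positive weight to 1; the diagonal is forced to zero.

    This yields the structural adjacency matrix used by the controllability
    machinery, which depends only on the presence of links, not strengths.
    """
    a = (net.weights > 0).astype(np.int8)
    if np.any(np.diag(a)):
        warnings.warn("self-loop weights discarded during binarization",
                      stacklevel=2)
    np.fill_diagonal(a, 0)
    return BinaryDirectedNetwork(adjacency=a, labels=net.labels)


def bidirect(net: BinaryDirectedNetwork) -> BinaryDirectedNetwork:
    """Replace every undirected link (i-j) by the two directed links i->j, j->i.

    Idempotent: symmetric input is returned unchanged (as a copy).
    """
    a = net.adjacency
    sym = ((a | a.T) > 0).astype(np.int8)
    np.fill_diagonal(sym, 0)
    return BinaryDirectedNetwork(adjacency=sym, labels=net.labels)


def remove_isolated(
        net: BinaryDirectedNetwork
) -> tuple[BinaryDirectedNetwork, list[str]]:
    """Drop zero-degree nodes; returns the reduced network and removed labels.

    Isolated regions carry no links, so they cannot influence distances or
    control chains; they only inflate the required number of input signals.
    """
    deg = net.in_degrees + net.out_degrees
    keep = np.nonzero(deg > 0)[0]
    removed = [net.label_of(i) for i in np.nonzero(deg == 0)[0]]
    sub = net.adjacency[np.ix_(keep, keep)]
    labels = [net.labels[i] for i in keep] if net.labels is not None else None
    return BinaryDirectedNetwork(adjacency=sub, labels=labels), removed


# ---------------------------------------------------------------------------
# Property statistics

def distance_matrix(net: BinaryDirectedNetwork) -> np.ndarray:
    """All-pairs directed shortest-path lengths; ``inf`` marks unreachable."""
    # csgraph wants M[i, j] = edge i->j, i.e. the transpose of our storage.
    g = csr_matrix(net.adjacency.T)
    return shortest_path(g, method="D", unweighted=True)


def heterogeneity(net: BinaryDirectedNetwork, r_const: float = 1.0) -> float:
    """Degree heterogeneity H = max(H_in, H_out) with
    H = (1 / (r N^2)) * sum_ij |k_i - k_j|.

    With ``r_const=1`` this is the mean absolute pairwise degree difference;
    passing ``r_const=mean_degree`` gives the density-normalized variant.
    """
    if r_const <= 0:
        raise ValueError("r_const must be positive")
    n = net.n_nodes

    def _h(k: np.ndarray) -> float:
        k = np.sort(k.astype(float))
        # sum_ij |k_i - k_j| = 2 * sum_i (2i - n + 1) k_(i)  for sorted k
        coef = 2 * np.arange(n) - n + 1
        return float(2 * np.dot(coef, k) / (r_const * n * n))

    return max(_h(net.in_degrees), _h(net.out_degrees))


def properties(net: BinaryDirectedNetwork,
               r_const: float = 1.0) -> NetworkProperties:
    """Structural summary: link count, isolated regions, degree statistics,
    heterogeneity, and mean directed distance over reachable ordered pairs.
    """
    if net.n_nodes == 0:
        raise ValueError("properties undefined for an empty network")
    deg_total = net.in_degrees + net.out_degrees
    isolated = [net.label_of(i) for i in np.nonzero(deg_total == 0)[0]]
    d = distance_matrix(net)
    off = ~np.eye(net.n_nodes, dtype=bool)
    finite = np.isfinite(d) & off
    mean_dist = float(d[finite].mean()) if finite.any() else math.nan
    out_deg = net.out_degrees
    return NetworkProperties(
        n_nodes=net.n_nodes,
        n_links=net.n_links,
        isolated_nodes=isolated,
        heterogeneity=heterogeneity(net, r_const),
        mean_degree=net.n_links / net.n_nodes,
        k_min=int(out_deg.min()),
        k_max=int(out_deg.max()),
        mean_distance=mean_dist,
    )


def properties_table(nets: Sequence[BinaryDirectedNetwork],
                     r_const: float = 1.0) -> pd.DataFrame:
    """Properties of several networks as one table (one row per network)."""
    rows = []
    for k, net in enumerate(nets, start=1):
        p = properties(net, r_const)
        rows.append({
            "network": k, "N": p.n_nodes, "E": p.n_links,
            "isolated": ";".join(p.isolated_nodes), "H": p.heterogeneity,
            "c": p.mean_degree, "k_min": p.k_min, "k_max": p.k_max,
            "d": p.mean_distance,
        })
    return pd.DataFrame(rows)
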