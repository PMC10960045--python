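"""Minimum driver signals by maximum matching, and the controllability Gramian.

For linear dynamics x' = Ax + Bu on a directed network, the minimum number of
independent control signals that guarantees structural controllability equals
``max(1, N_u)`` where ``N_u`` is the number of unmatched nodes in a maximum
matching of the bipartite split-node representation of the network.  For a
concrete input set S the system is controllable on [0, t_f] iff the
controllability Gramian

    W_B(t_f) = int_0^{t_f} exp(A tau) B B^T exp(A^T tau) d tau

is positive definite; its smallest eigenvalue is the numerical test statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.linalg import expm

from .network_model import BinaryDirectedNetwork


@dataclass(frozen=True)
class BipartiteRepresentation:
    """Split-node bipartite graph: node v becomes an out-copy v+ and an
    in-copy v-; a directed link v->w becomes the undirected pair (v+, w-)."""

    n_nodes: int
    links: frozenset[tuple[int, int]]  # (v_out, w_in), 0-based


@dataclass
class MatchingResult:
    matched_links: frozenset[tuple[int, int]]
    unmatched_nodes: tuple[int, ...]  # in-copies with no matched link
    n_inputs: int                     # max(1, N_u)

    @property
    def n_unmatched(self) -> int:
        return len(self.unmatched_nodes)


@dataclass(frozen=True)
class InputSet:
    """The driver-node set S; B is the n x m unit-column selector matrix."""

    nodes: tuple[int, ...]

    def __init__(self, nodes) -> None:
        nodes = tuple(sorted(set(int(v) for v in nodes)))
        if not nodes:
            raise ValueError("input set must be nonempty")
        object.__setattr__(self, "nodes", nodes)

    def b_matrix(self, n: int) -> np.ndarray:
        if max(self.nodes) >= n or min(self.nodes) < 0:
            raise ValueError("input node index out of range")
        b = np.zeros((n, len(self.nodes)))
        for col, v in enumerate(self.nodes):
            b[v, col] = 1.0
        return b


@dataclass
class GramianResult:
    """Finite-horizon controllability Gramian and its trace-energy summaries.

    ``trace_energy`` is epsilon(t_f) = Trace(W_B(t_f)); larger values mean
    less average energy is needed to move the state in all directions.
    """

    W: np.ndarray
    lambda_min: float
    trace_energy: float
    t_f: float

    @property
    def log10_energy(self) -> float:
        return float(np.log10(self.trace_energy))

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]


def build_bipartite(net: BinaryDirectedNetwork) -> BipartiteRepresentation:
    """Construct the split-node bipartite representation of the network."""
    links = frozenset((int(i), int(j)) for i, j in net.edges())
    return BipartiteRepresentation(n_nodes=net.n_nodes, links=links)


def maximum_matching(bip: BipartiteRepresentation) -> MatchingResult:
    """Maximum matching via Hopcroft–Karp; deterministic for a fixed network.

    Unmatched in-copies mark the nodes where independent external signals
    must attach; their count N_u is invariant across maximum matchings.
    """
    g = nx.Graph()
    out_nodes = [("out", v) for v in range(bip.n_nodes)]
    in_nodes = [("in", v) for v in range(bip.n_nodes)]
    g.add_nodes_from(out_nodes, bipartite=0)
    g.add_nodes_from(in_nodes, bipartite=1)
    for v, w in sorted(bip.links):
        g.add_edge(("out", v), ("in", w))
    m = nx.bipartite.hopcroft_karp_matching(g, top_nodes=out_nodes)
    matched = frozenset(
        (u[1], w[1]) for u, w in m.items() if u[0] == "out")
    matched_in = {w for _, w in matched}
    unmatched = tuple(v for v in range(bip.n_nodes) if v not in matched_in)
    return MatchingResult(
        matched_links=matched,
        unmatched_nodes=unmatched,
        n_inputs=max(1, len(unmatched)),
    )


def enumerate_unmatched_sets(bip: BipartiteRepresentation,
                             max_links: int = 64) -> set[frozenset[int]]:
    """Enumerate the unmatched in-copy sets of *all* maximum matchings.

    Exponential in the worst case; intended for small networks (used to
    exhibit alternative input sets and as a test oracle).
    """
    links = sorted(bip.links)
    if len(links) > max_links:
        raise ValueError(f"too many links ({len(links)}) for enumeration")
    best_size = maximum_matching(bip).n_unmatched
    target = bip.n_nodes - best_size  # matching size of any maximum matching
    sets: set[frozenset[int]] = set()

    def rec(idx: int, used_out: set[int], used_in: set[int], size: int) -> None:
        remaining = len(links) - idx
        if size + remaining < target:
            return
        if size == target:
            sets.add(frozenset(v for v in range(bip.n_nodes)
                               if v not in used_in))
            return
        if idx == len(links):
            return
        v, w = links[idx]
        if v not in used_out and w not in used_in:
            used_out.add(v); used_in.add(w)
            rec(idx + 1, used_out, used_in, size + 1)
            used_out.remove(v); used_in.remove(w)
        rec(idx + 1, used_out, used_in, size)

    rec(0, set(), set(), 0)
    return sets


def gramian(net: BinaryDirectedNetwork, inputs: InputSet,
            t_f: float = 1.0) -> GramianResult:
    """Controllability Gramian by the Van Loan block-exponential identity.

    exp(t_f * [[-A, B B^T], [0, A^T]]) has upper-right block F12 and
    lower-right block F22 with W_B(t_f) = F22^T @ F12 — exact up to the
    accuracy of the matrix exponential, valid for unstable A (no Lyapunov
    equation is involved).
    """
    if t_f <= 0:
        raise ValueError("t_f must be positive")
    a = net.adjacency.astype(float)
    n = net.n_nodes
    b = inputs.b_matrix(n)
    q = b @ b.T
    block = np.zeros((2 * n, 2 * n))
    block[:n, :n] = -a
    block[:n, n:] = q
    block[n:, n:] = a.T
    f = expm(block * t_f)
    if not np.all(np.isfinite(f)):
        raise FloatingPointError(
            "matrix exponential overflowed; use a smaller t_f or rescale A")
    w = f[n:, n:].T @ f[:n, n:]
    w = (w + w.T) / 2.0  # enforce symmetry to machine tolerance
    lam_min = float(np.linalg.eigvalsh(w)[0])
    return GramianResult(W=w, lambda_min=lam_min,
                         trace_energy=float(np.trace(w)), t_f=t_f)


def kalman_rank(net: BinaryDirectedNetwork, inputs: InputSet) -> int:
    """Rank of the Kalman controllability matrix [B, AB, ..., A^{n-1}B]."""
    a = net.adjacency.astype(float)
    n = net.n_nodes
    b = inputs.b_matrix(n)
    blocks = [b]
    for _ in range(n - 1):
        b = a @ b
        nrm = np.abs(b).max()
        if nrm > 0:
            b = b / nrm  # scale to keep the rank computation conditioned
        blocks.append(b)
    return int(np.linalg.matrix_rank(np.hstack(blocks)))


@dataclass
class ControllabilityDiagnostics:
    controllable: bool
    lambda_min: float
    tol: float
    kalman_rank: int
    n_nodes: int


def is_structurally_controllable(
        net: BinaryDirectedNetwork, inputs: InputSet, t_f: float = 1.0,
        tol: float | None = None) -> ControllabilityDiagnostics:
    """Gramian positivity test: controllable iff lambda_min(W) > tol.

    The Gramian of dense networks is typically ill-conditioned, so the
    default tolerance scales with the largest eigenvalue:
    ``tol = n * eps * lambda_max(W)``.  The Kalman rank is reported as an
    independent cross-check (rank n iff controllable, for exact arithmetic).
    """
    g = gramian(net, inputs, t_f)
    lam = np.linalg.eigvalsh(g.W)
    if tol is None:
        tol = g.n_nodes * np.finfo(float).eps * max(float(lam[-1]), 0.0)
    if tol < 0:
        raise ValueError("tol must be non-negative")
    return ControllabilityDiagnostics(
        controllable=bool(g.lambda_min > tol),
        lambda_min=g.lambda_min,
        tol=float(tol),
        kalman_rank=kalman_rank(net, inputs),
        n_nodes=g.n_nodes,
    )
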