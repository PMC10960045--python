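"""Degree-preserving null models and rich-club destruction.

Randomization uses double-edge swaps: two links (a-b), (c-d) are replaced by
(a-d), (c-b), preserving every node's degree while scrambling higher-order
structure.  Symmetric (bidirectional) networks are rewired on their
undirected skeleton, with both directions written back, so bidirectionality
is preserved; asymmetric digraphs are rewired arc-wise, preserving in- and
out-degree separately.  The trial budget is ceil((|E|/2) * ln(1/epsilon))
with |E| the directed link count; rejected proposals (self-loops or
duplicate links) count toward the budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network_model import BinaryDirectedNetwork
from .placement import min_inputs_for_lcc


@dataclass
class RewiringConfig:
    epsilon: float = 1e-6
    n_replicates: int = 20
    hub_quantile: float = 0.1   # top fraction of nodes treated as hubs
    seed: int | None = 0

    def __post_init__(self) -> None:
        if not (1e-7 <= self.epsilon <= 1e-6):
            raise ValueError("epsilon must lie in [1e-7, 1e-6]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if not (0 < self.hub_quantile < 1):
            raise ValueError("hub_quantile must be in (0, 1)")

    def trial_count(self, n_links: int) -> int:
        """ceil((|E|/2) * ln(1/epsilon)), |E| = directed link count."""
        return math.ceil(n_links / 2 * math.log(1.0 / self.epsilon))


@dataclass
class RewiringDiagnostics:
    trials: int
    accepted: int
    rejected: int


def _undirected_edges(a: np.ndarray) -> list[tuple[int, int]]:
    iu, ju = np.nonzero(np.triu(a, k=1))
    return [(int(i), int(j)) for i, j in zip(iu, ju)]


def _rewire_symmetric(a: np.ndarray, trials: int,
                      rng: np.random.Generator) -> RewiringDiagnostics:
    edges = _undirected_edges(a)
    m = len(edges)
    accepted = 0
    for _ in range(trials):
        e1, e2 = rng.integers(m), rng.integers(m)
        if e1 == e2:
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if rng.integers(2):
            x, y = y, x
        # propose (u, x), (v, y)
        if len({u, v, x, y}) < 4 or a[u, x] or a[v, y]:
            continue
        a[u, v] = a[v, u] = a[x, y] = a[y, x] = 0
        a[u, x] = a[x, u] = a[v, y] = a[y, v] = 1
        edges[e1] = (min(u, x), max(u, x))
        edges[e2] = (min(v, y), max(v, y))
        accepted += 1
    return RewiringDiagnostics(trials=trials, accepted=accepted,
                               rejected=trials - accepted)


def _rewire_directed(a: np.ndarray, trials: int,
                     rng: np.random.Generator) -> RewiringDiagnostics:
    tgt, src = np.nonzero(a)
    arcs = [(int(s), int(t)) for s, t in zip(src, tgt)]
    m = len(arcs)
    accepted = 0
    for _ in range(trials):
        e1, e2 = rng.integers(m), rng.integers(m)
        if e1 == e2:
            continue
        u, v = arcs[e1]   # u -> v
        x, y = arcs[e2]   # x -> y
        # propose u -> y, x -> v
        if u == y or x == v or a[y, u] or a[v, x]:
            continue
        a[v, u] = a[y, x] = 0
        a[y, u] = a[v, x] = 1
        arcs[e1] = (u, y)
        arcs[e2] = (x, v)
        accepted += 1
    return RewiringDiagnostics(trials=trials, accepted=accepted,
                               rejected=trials - accepted)


def degree_preserving_rewire(
        net: BinaryDirectedNetwork, cfg: RewiringConfig,
        rng: np.random.Generator | None = None,
        return_diagnostics: bool = False):
    """Randomize wiring while preserving every node's in/out degree."""
    if net.n_links < 2:
        raise ValueError("need at least 2 links to rewire")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    a = net.adjacency.copy()
    trials = cfg.trial_count(net.n_links)
    if net.is_symmetric:
        diag = _rewire_symmetric(a, trials, rng)
    else:
        diag = _rewire_directed(a, trials, rng)
    out = BinaryDirectedNetwork(adjacency=a, labels=net.labels)
    return (out, diag) if return_diagnostics else out


def hub_nodes(net: BinaryDirectedNetwork, hub_quantile: float) -> np.ndarray:
    """Indices of the top ``hub_quantile`` fraction of nodes by degree."""
    n_hubs = max(1, math.ceil(hub_quantile * net.n_nodes))
    deg = net.degrees
    order = sorted(range(net.n_nodes), key=lambda v: (-deg[v], v))
    return np.array(order[:n_hubs])


def hub_hub_link_count(net: BinaryDirectedNetwork,
                       hub_quantile: float = 0.1) -> int:
    """Number of undirected links between hub nodes."""
    hubs = hub_nodes(net, hub_quantile)
    sub = net.adjacency[np.ix_(hubs, hubs)]
    return int(np.triu((sub | sub.T) > 0, k=1).sum())


def break_rich_club(net: BinaryDirectedNetwork, cfg: RewiringConfig,
                    rng: np.random.Generator | None = None
                    ) -> BinaryDirectedNetwork:
    """Remove hub assortativity by targeted degree-preserving swaps.

    Repeatedly pick a hub–hub link and a link between two small-degree
    (non-hub) nodes and rewire them into two hub–low links.  The hub–hub
    link count is non-increasing and the degree sequence is unchanged.
    Stops when no swappable pair remains or the trial budget is spent.
    Operates on the undirected skeleton (symmetric networks only).
    """
    if not net.is_symmetric:
        raise ValueError("break_rich_club expects a symmetric network")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    a = net.adjacency.copy()
    hubs = set(hub_nodes(net, cfg.hub_quantile).tolist())
    budget = cfg.trial_count(net.n_links)
    for _ in range(budget):
        edges = _undirected_edges(a)
        hh = [(u, v) for u, v in edges if u in hubs and v in hubs]
        ll = [(u, v) for u, v in edges if u not in hubs and v not in hubs]
        if not hh or not ll:
            break
        done = False
        order_hh = rng.permutation(len(hh))
        order_ll = rng.permutation(len(ll))
        for ih in order_hh:
            u, v = hh[ih]
            for il in order_ll:
                x, y = ll[il]
                for (p, q) in ((x, y), (y, x)):
                    # propose hub-low links (u, p), (v, q)
                    if len({u, v, p, q}) < 4 or a[u, p] or a[v, q]:
                        continue
                    a[u, v] = a[v, u] = a[p, q] = a[q, p] = 0
                    a[u, p] = a[p, u] = a[v, q] = a[q, v] = 1
                    done = True
                    break
                if done:
                    break
            if done:
                break
        if not done:
            break
    return BinaryDirectedNetwork(adjacency=a, labels=net.labels)


def randomized_ensemble_inputs(
        net: BinaryDirectedNetwork, ell: int, cfg: RewiringConfig,
        remove_rich_club: bool = True,
        ) -> tuple[float, list[float]]:
    """Fraction of inputs needed for LCC <= ell on randomized replicates.

    For each of ``cfg.n_replicates`` degree-preserving randomizations
    (optionally followed by rich-club removal), run the greedy placement
    and record |S|/N; returns the ensemble mean and per-replicate values.
    """
    rng = np.random.default_rng(cfg.seed)
    fractions: list[float] = []
    for _ in range(cfg.n_replicates):
        r = degree_preserving_rewire(net, cfg, rng=rng)
        if remove_rich_club:
            r = break_rich_club(r, cfg, rng=rng)
        res = min_inputs_for_lcc(r, ell, mode="greedy",
                                 verify_controllability=False)
        fractions.append(res.n_i_fraction)
    return float(np.mean(fractions)), fractions
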