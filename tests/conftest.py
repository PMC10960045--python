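import numpy as np
import pytest

from braincontrol import BinaryDirectedNetwork, fig1_toy
from braincontrol.controllability import InputSet


@pytest.fixture
def toy():
    """5-node worked example: 1->2, 2->3, 2->4, 4->5."""
    return fig1_toy()


@pytest.fixture
def chain2():
    """Two-node directed chain 1->2 with the closed-form Gramian."""
    return BinaryDirectedNetwork(np.array([[0, 0], [1, 0]], dtype=np.int8))


@pytest.fixture
def star4():
    """Bidirected star: center 0 linked to leaves 1..3."""
    a = np.zeros((4, 4), dtype=np.int8)
    for leaf in (1, 2, 3):
        a[0, leaf] = a[leaf, 0] = 1
    return BinaryDirectedNetwork(a)


def make_net(edges, n):
    """Directed network from (source, target) pairs."""
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        a[j, i] = 1
    return BinaryDirectedNetwork(a)


def random_digraph(rng, n, p=0.25):
    a = (rng.random((n, n)) < p).astype(np.int8)
    np.fill_diagonal(a, 0)
    return BinaryDirectedNetwork(a)


def random_symmetric(rng, n, p=0.3):
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = ((a + a.T) > 0).astype(np.int8)
    np.fill_diagonal(a, 0)
    return BinaryDirectedNetwork(a)


def brute_force_matching_size(net):
    """Exhaustive maximum matching size on the split-node bipartite graph."""
    edges = net.edges()

    def rec(idx, used_out, used_in):
        if idx == len(edges):
            return 0
        best = rec(idx + 1, used_out, used_in)
        v, w = edges[idx]
        if v not in used_out and w not in used_in:
            best = max(best, 1 + rec(idx + 1, used_out | {v}, used_in | {w}))
        return best

    return rec(0, frozenset(), frozenset())


def bfs_distances_from(net, source):
    """Plain BFS oracle along link direction (source -> successors)."""
    from collections import deque

    n = net.n_nodes
    dist = [float("inf")] * n
    dist[source] = 0
    dq = deque([source])
    while dq:
        v = dq.popleft()
        for w in np.nonzero(net.adjacency[:, v])[0]:
            if dist[w] == float("inf"):
                dist[w] = dist[v] + 1
                dq.append(int(w))
    return dist


def min_cover_brute(net, ell):
    """Smallest distance-ell dominating set by subset enumeration."""
    from itertools import combinations

    n = net.n_nodes
    dists = [bfs_distances_from(net, v) for v in range(n)]
    for k in range(1, n + 1):
        for subset in combinations(range(n), k):
            if all(min(dists[v][w] for v in subset) <= ell
                   for w in range(n)):
                return subset
    return tuple(range(n))
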