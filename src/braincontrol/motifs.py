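"""Census of the two connected 3-node patterns of bidirectional networks.

On a bidirectional (symmetric) network the only connected induced 3-node
subgraphs are the mutual open path a<->b<->c (triad id 78) and the fully
mutual triangle (triad id 238).  Their total M proxies the number of
alternative paths between regions: each extra pattern gives inputs an
additional route to reach other nodes, which lowers the control energy.

Counts are of *induced* subgraphs.  For symmetric networks closed forms are
used: id238 equals the triangle count T = trace(A^3)/6 and
id78 = sum_v C(k_v, 2) - 3T with k_v the undirected degree.  Asymmetric
digraphs fall back to triple enumeration, with connected triads containing
any non-mutual link tallied separately as "other".
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .network_model import BinaryDirectedNetwork


@dataclass
class MotifCensus:
    count_id78: int    # mutual open path a<->b<->c, no a-c link
    count_id238: int   # fully mutually connected triple
    count_other: int   # connected triads with a non-mutual link (digraphs)

    @property
    def M(self) -> int:
        return self.count_id78 + self.count_id238


def _census_symmetric(a: np.ndarray) -> MotifCensus:
    af = a.astype(np.int64)
    triangles = int(np.trace(af @ af @ af)) // 6
    k = af.sum(axis=1)
    open_paths = int((k * (k - 1) // 2).sum()) - 3 * triangles
    return MotifCensus(count_id78=open_paths, count_id238=triangles,
                       count_other=0)


def _census_enumerate(a: np.ndarray) -> MotifCensus:
    n = a.shape[0]
    mutual = (a & a.T).astype(bool)
    any_link = (a | a.T).astype(bool)
    # restrict to nodes with at least one link
    active = [v for v in range(n) if any_link[v].any()]
    c78 = c238 = other = 0
    for i, j, k in combinations(active, 3):
        links = int(any_link[i, j]) + int(any_link[i, k]) + int(any_link[j, k])
        if links < 2:
            continue  # disconnected triple
        mut = int(mutual[i, j]) + int(mutual[i, k]) + int(mutual[j, k])
        if mut == 3:
            c238 += 1
        elif mut == 2 and links == 2:
            c78 += 1
        else:
            other += 1
    return MotifCensus(count_id78=c78, count_id238=c238, count_other=other)


def motif_census(net: BinaryDirectedNetwork) -> MotifCensus:
    """Count induced 3-node patterns; closed forms on symmetric networks."""
    a = np.asarray(net.adjacency, dtype=np.int8)
    if net.is_symmetric:
        return _census_symmetric(a)
    return _census_enumerate(a)
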