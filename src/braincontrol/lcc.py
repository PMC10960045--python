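"""Longest control chain (LCC) and per-node input distances.

The LCC of an input set S is ``max_w min_{v in S} d(v, w)``: the longest
directed distance from any node to its nearest input, measured *from* the
input *toward* the controlled node.  Control energy grows sharply with the
LCC, which makes it the structural handle for input-node placement.  On the
symmetric (bidirectional) networks built from connectomes the direction
convention is invisible, but it matters for general digraphs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .controllability import InputSet
from .network_model import BinaryDirectedNetwork, distance_matrix


@dataclass
class DistanceProfile:
    """Per-node distance to the nearest input, and their maximum (the LCC)."""

    distances: np.ndarray  # float; np.inf for nodes unreachable from S
    inputs: tuple[int, ...]

    @property
    def lcc(self) -> float:
        """Max over nodes of the distance to the nearest input; may be inf."""
        return float(self.distances.max()) if self.distances.size else 0.0

    @property
    def is_finite(self) -> bool:
        return bool(np.isfinite(self.distances).all())


def input_distances(net: BinaryDirectedNetwork,
                    inputs: InputSet) -> DistanceProfile:
    """Multi-source BFS along link direction from the input set.

    ``distances[w] = min_{v in S} d(v, w)``; inputs themselves are at 0.
    Unreachable nodes get ``inf`` (used as an infeasibility signal by the
    placement search rather than raising).
    """
    g = csr_matrix(net.adjacency.T)  # csgraph convention: M[i, j] = i -> j
    d = shortest_path(g, method="D", unweighted=True,
                      indices=list(inputs.nodes))
    dmin = np.asarray(d).min(axis=0)
    return DistanceProfile(distances=dmin, inputs=inputs.nodes)


@dataclass
class SingleInputScanResult:
    """LCC obtainable from each node as the sole input (its eccentricity)."""

    eccentricities: np.ndarray  # float; inf if the node cannot reach everyone
    lcc_min: float
    lcc_max: float
    argmin_nodes: tuple[int, ...]
    argmax_nodes: tuple[int, ...]


def lcc_range_single_input(net: BinaryDirectedNetwork) -> SingleInputScanResult:
    """Smallest and largest achievable LCC with a single input node.

    For each node v the LCC of S = {v} is the BFS eccentricity of v; nodes
    that cannot reach the whole network have infinite eccentricity and are
    excluded from the extremes (all-infinite networks report inf extremes).
    """
    d = distance_matrix(net)
    ecc = d.max(axis=1)
    finite = np.isfinite(ecc)
    if finite.any():
        lcc_min = float(ecc[finite].min())
        lcc_max = float(ecc[finite].max())
        argmin = tuple(int(i) for i in np.nonzero(ecc == lcc_min)[0])
        argmax = tuple(int(i) for i in
                       np.nonzero(finite & (ecc == lcc_max))[0])
    else:
        lcc_min = lcc_max = math.inf
        argmin = argmax = ()
    return SingleInputScanResult(
        eccentricities=ecc, lcc_min=lcc_min, lcc_max=lcc_max,
        argmin_nodes=argmin, argmax_nodes=argmax)
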