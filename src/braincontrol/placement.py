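"""Input-node placement under a longest-control-chain constraint.

Finding the fewest inputs that achieve LCC <= l is the minimum distance-l
dominating-set problem: choose the smallest S such that every node lies
within directed distance l of some member of S.  The module provides an
exact branch-and-bound search (small networks), a greedy max-coverage
heuristic, the naive hub-first baseline (add nodes in descending degree
order), and dispersion statistics of the chosen sets.  Every returned set is
re-verified through the lcc module, and structural controllability of
(A, B_S) is confirmed with the Gramian test, augmenting from unmatched
matching nodes in the rare case the cover alone is insufficient.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .controllability import (InputSet, build_bipartite,
                              is_structurally_controllable, maximum_matching)
from .lcc import input_distances
from .network_model import BinaryDirectedNetwork, distance_matrix

# Gramian verification is skipped above this size by default: the check is
# O(n^3) per candidate set and adds nothing on symmetric connected networks,
# where a cover touching every component is structurally sufficient.
_VERIFY_MAX_N = 200


@dataclass
class PlacementResult:
    """An input set achieving a target LCC, with provenance and dispersion."""

    inputs: tuple[int, ...]
    method: str                    # exact | greedy-cover | hub-greedy | hub-matched
    target_lcc: float
    achieved_lcc: float
    n_nodes: int
    degrees_of_inputs: tuple[int, ...] = ()
    mean_pairwise_input_distance: float | None = None
    pairwise_input_distance_std: float | None = None
    controllable: bool | None = None
    augmented_nodes: tuple[int, ...] = ()

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)

    @property
    def n_i_fraction(self) -> float:
        return self.n_inputs / self.n_nodes


def _coverage_balls(net: BinaryDirectedNetwork, ell: int) -> list[int]:
    """Bitmask per node v of the nodes within directed distance ell of v."""
    d = distance_matrix(net)
    balls = []
    for v in range(net.n_nodes):
        mask = 0
        for w in np.nonzero(d[v] <= ell)[0]:
            mask |= 1 << int(w)
        balls.append(mask)
    return balls


def _dispersion(net: BinaryDirectedNetwork,
                nodes: tuple[int, ...]) -> tuple[float | None, float | None]:
    """Mean and std of directed shortest-path distances over ordered input
    pairs (finite pairs only); None for sets of size < 2."""
    if len(nodes) < 2:
        return None, None
    d = distance_matrix(net)
    idx = np.array(nodes)
    sub = d[np.ix_(idx, idx)]
    off = ~np.eye(len(idx), dtype=bool)
    vals = sub[off]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return None, None
    return float(vals.mean()), float(vals.std())


def _finalize(net: BinaryDirectedNetwork, nodes: tuple[int, ...], method: str,
              ell: float, t_f: float = 1.0,
              verify_controllability: bool | None = None) -> PlacementResult:
    nodes = tuple(sorted(nodes))
    prof = input_distances(net, InputSet(nodes))
    controllable: bool | None = None
    augmented: tuple[int, ...] = ()
    if verify_controllability is None:
        verify_controllability = net.n_nodes <= _VERIFY_MAX_N
    if verify_controllability:
        diag = is_structurally_controllable(net, InputSet(nodes), t_f=t_f)
        controllable = diag.controllable
        if not controllable:
            # Attach signals at unmatched matching nodes not already covered.
            mr = maximum_matching(build_bipartite(net))
            extra = tuple(v for v in mr.unmatched_nodes if v not in nodes)
            if extra:
                augmented = extra
                nodes = tuple(sorted(set(nodes) | set(extra)))
                prof = input_distances(net, InputSet(nodes))
                controllable = is_structurally_controllable(
                    net, InputSet(nodes), t_f=t_f).controllable
    deg = net.degrees
    mean_d, std_d = _dispersion(net, nodes)
    return PlacementResult(
        inputs=nodes, method=method, target_lcc=ell,
        achieved_lcc=prof.lcc, n_nodes=net.n_nodes,
        degrees_of_inputs=tuple(sorted(int(deg[v]) for v in nodes)),
        mean_pairwise_input_distance=mean_d,
        pairwise_input_distance_std=std_d,
        controllable=controllable, augmented_nodes=augmented)


def _greedy_cover(net: BinaryDirectedNetwork, ell: int,
                  rng: np.random.Generator | None = None) -> tuple[int, ...]:
    """Greedy max-coverage l-cover.  Deterministic ties: larger degree, then
    lower index; with ``rng`` the tie pool is sampled uniformly instead."""
    n = net.n_nodes
    balls = _coverage_balls(net, ell)
    full = (1 << n) - 1
    deg = net.degrees
    covered = 0
    chosen: list[int] = []
    while covered != full:
        gains = [(balls[v] | covered).bit_count() - covered.bit_count()
                 if v not in chosen else -1 for v in range(n)]
        best = max(gains)
        if best <= 0:
            # Only possible if some node is uncovered and uncoverable, which
            # cannot happen (every node covers itself at distance 0).
            raise RuntimeError("greedy cover stalled")
        pool = [v for v in range(n) if gains[v] == best]
        if rng is not None:
            pick = int(pool[rng.integers(len(pool))])
        else:
            pick = max(pool, key=lambda v: (deg[v], -v))
        chosen.append(pick)
        covered |= balls[pick]
    return tuple(sorted(chosen))


def _exact_covers(net: BinaryDirectedNetwork, ell: int,
                  max_nodes: int = 25,
                  max_solutions: int = 200) -> list[tuple[int, ...]]:
    """All minimum l-covers (capped) by branch and bound over bitmasks.

    Branches on the uncovered node with the fewest potential coverers; the
    greedy solution provides the initial upper bound.  Every cover must
    contain a coverer of the branching node, so the enumeration of
    minimum-size covers is complete (up to the cap).
    """
    n = net.n_nodes
    if n > max_nodes:
        raise ValueError(
            f"exact search limited to {max_nodes} nodes (got {n}); "
            "use mode='greedy'")
    balls = _coverage_balls(net, ell)
    full = (1 << n) - 1
    # coverers[w] = nodes whose ball contains w
    coverers = [[v for v in range(n) if balls[v] >> w & 1] for w in range(n)]
    max_ball = max(b.bit_count() for b in balls)
    best_size = [len(_greedy_cover(net, ell))]
    sols: set[tuple[int, ...]] = set()

    def rec(covered: int, chosen: list[int]) -> None:
        if covered == full:
            if len(chosen) < best_size[0]:
                best_size[0] = len(chosen)
                sols.clear()
            if len(chosen) == best_size[0] and len(sols) < max_solutions:
                sols.add(tuple(sorted(chosen)))
            return
        if len(chosen) >= best_size[0]:
            return
        unc = [w for w in range(n) if not covered >> w & 1]
        if len(chosen) + math.ceil(len(unc) / max_ball) > best_size[0]:
            return
        w = min(unc, key=lambda x: len(coverers[x]))
        for v in coverers[w]:
            chosen.append(v)
            rec(covered | balls[v], chosen)
            chosen.pop()

    rec(0, [])
    if not sols:
        sols.add(_greedy_cover(net, ell))  # greedy already optimal
    return sorted(sols)


def min_inputs_for_lcc(net: BinaryDirectedNetwork, ell: int,
                       mode: str = "greedy",
                       rng: np.random.Generator | None = None,
                       t_f: float = 1.0,
                       verify_controllability: bool | None = None
                       ) -> PlacementResult:
    """Smallest (mode='exact') or near-smallest (mode='greedy') input set
    with LCC <= ell.

    ell = 0 forces S = V.  If the only feasible cover is the full node set,
    it is returned with a warning.  In exact mode, when several minimum
    covers exist and controllability verification is on, a cover passing
    the Gramian test is preferred over one that would need augmentation.
    """
    if ell < 0:
        raise ValueError("ell must be non-negative")
    if net.n_nodes == 0:
        raise ValueError("network is empty")
    if verify_controllability is None:
        verify_controllability = net.n_nodes <= _VERIFY_MAX_N
    if ell == 0:
        nodes = tuple(range(net.n_nodes))
    elif mode == "exact":
        sols = _exact_covers(net, ell)
        nodes = sols[0]
        if verify_controllability:
            for cand in sols:
                if is_structurally_controllable(
                        net, InputSet(cand), t_f=t_f).controllable:
                    nodes = cand
                    break
    elif mode == "greedy":
        nodes = _greedy_cover(net, ell, rng=rng)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(nodes) == net.n_nodes and ell > 0:
        warnings.warn(f"LCC <= {ell} requires every node as an input",
                      stacklevel=2)
    method = "exact" if mode == "exact" and ell > 0 else "greedy-cover"
    if ell == 0:
        method = "exact"
    return _finalize(net, nodes, method, ell, t_f=t_f,
                     verify_controllability=verify_controllability)


def hub_greedy_for_lcc(net: BinaryDirectedNetwork, ell: int,
                       t_f: float = 1.0,
                       verify_controllability: bool | None = None
                       ) -> PlacementResult:
    """Naive baseline: add nodes in descending degree order (ties by
    ascending index) until the LCC drops to ell."""
    if ell < 0:
        raise ValueError("ell must be non-negative")
    deg = net.degrees
    order = sorted(range(net.n_nodes), key=lambda v: (-deg[v], v))
    chosen: list[int] = []
    for v in order:
        chosen.append(v)
        if input_distances(net, InputSet(chosen)).lcc <= ell:
            break
    return _finalize(net, tuple(chosen), "hub-greedy", ell, t_f=t_f,
                     verify_controllability=verify_controllability)


def matched_size_hub_set(net: BinaryDirectedNetwork,
                         reference: PlacementResult | int,
                         t_f: float = 1.0,
                         verify_controllability: bool = False
                         ) -> PlacementResult:
    """Degree-descending prefix of the same cardinality as ``reference``.

    Used to contrast the dispersion of an optimal input set with that of an
    equally sized all-hub set (hubs in a rich club sit at mutual distance 1).
    """
    size = reference if isinstance(reference, int) else reference.n_inputs
    if size < 1 or size > net.n_nodes:
        raise ValueError("reference size out of range")
    deg = net.degrees
    order = sorted(range(net.n_nodes), key=lambda v: (-deg[v], v))
    target = reference.target_lcc if isinstance(reference, PlacementResult) \
        else math.nan
    return _finalize(net, tuple(order[:size]), "hub-matched", target,
                     t_f=t_f, verify_controllability=verify_controllability)


@dataclass
class CensusResult:
    """Node participation across many near-minimal l-cover input sets."""

    counts: np.ndarray            # per-node participation count
    n_sets: int                   # distinct sets actually generated
    sets: tuple[tuple[int, ...], ...]
    primary_contributors: tuple[int, ...]  # nodes present in every set


def input_set_census(net: BinaryDirectedNetwork, ell: int, n_sets: int = 100,
                     seed: int | None = 0,
                     max_attempts_factor: int = 50) -> CensusResult:
    """Generate ``n_sets`` distinct near-minimal l-cover input sets by
    randomized greedy (uniform tie-breaking) and count node participation.

    Nodes appearing in every set are flagged as primary contributors: they
    are (empirically) forced by the network structure.  If fewer distinct
    sets exist within the attempt budget, all found are returned with a
    warning.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be positive")
    rng = np.random.default_rng(seed)
    found: dict[tuple[int, ...], None] = {}
    attempts = 0
    budget = max_attempts_factor * n_sets
    while len(found) < n_sets and attempts < budget:
        attempts += 1
        s = _greedy_cover(net, ell, rng=rng) if ell > 0 \
            else tuple(range(net.n_nodes))
        found.setdefault(s, None)
        if ell == 0:
            break
    sets = tuple(found.keys())
    if len(sets) < n_sets:
        warnings.warn(
            f"only {len(sets)} distinct input sets found "
            f"(requested {n_sets})", stacklevel=2)
    counts = np.zeros(net.n_nodes, dtype=int)
    for s in sets:
        counts[list(s)] += 1
    primary = tuple(int(v) for v in np.nonzero(counts == len(sets))[0])
    return CensusResult(counts=counts, n_sets=len(sets), sets=sets,
                        primary_contributors=primary)
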