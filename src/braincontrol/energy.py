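"""Trace-based control energy.

The average energy needed to steer the network in all state-space directions
is governed by Trace(W_B(t_f)^{-1}), but the Gramian of brain-like networks
is near-singular, so that quantity is numerically unusable.  The package
therefore reports epsilon(t_f) = Trace(W_B(t_f)), which obeys the inverse
proportionality Trace(W^{-1}) > N^2 / Trace(W): a *larger* trace means *less*
control energy.  Values are conventionally presented as log10(epsilon).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from .controllability import GramianResult, InputSet, gramian
from .network_model import BinaryDirectedNetwork

__all__ = ["GramianResult", "trace_energy", "per_node_trace_energies",
           "trace_inverse_check"]


def trace_energy(net: BinaryDirectedNetwork, inputs: InputSet,
                 t_f: float = 1.0) -> GramianResult:
    """Gramian with its trace energy epsilon(t_f) for the given input set."""
    return gramian(net, inputs, t_f)


def per_node_trace_energies(net: BinaryDirectedNetwork,
                            t_f: float = 1.0) -> np.ndarray:
    """epsilon({v}, t_f) for every node v, from one matrix exponential.

    The trace is additive over input columns:
    ``epsilon(S) = sum_{v in S} epsilon({v})`` because the Gramian of a
    multi-input B is the sum of the per-column Gramians.  Each single-input
    trace is a diagonal entry of G = int_0^{t_f} exp(A^T tau) exp(A tau) dtau,
    so all n of them come from a single Van Loan block exponential on
    (A^T, I) rather than n separate Gramian integrations.
    """
    if t_f <= 0:
        raise ValueError("t_f must be positive")
    a = net.adjacency.astype(float)
    n = net.n_nodes
    block = np.zeros((2 * n, 2 * n))
    block[:n, :n] = -a.T
    block[:n, n:] = np.eye(n)
    block[n:, n:] = a
    f = expm(block * t_f)
    if not np.all(np.isfinite(f)):
        raise FloatingPointError(
            "matrix exponential overflowed; use a smaller t_f or rescale A")
    g = f[n:, n:].T @ f[:n, n:]
    g = (g + g.T) / 2.0
    return np.diag(g).copy()


def trace_inverse_check(result: GramianResult,
                        tol: float | None = None
                        ) -> tuple[float, float, bool]:
    """Verify Trace(W^{-1}) >= N^2 / Trace(W) on a nonsingular Gramian.

    Returns (lhs, rhs, holds).  Equality occurs exactly at W proportional to
    the identity (Cauchy–Schwarz).  A singular W raises: the system is not
    controllable with the given inputs, so the average energy is infinite.
    """
    w = result.W
    n = w.shape[0]
    lam = np.linalg.eigvalsh(w)
    if tol is None:
        tol = n * np.finfo(float).eps * max(float(lam[-1]), 0.0)
    if lam[0] <= tol:
        raise np.linalg.LinAlgError(
            f"Gramian is singular to tolerance {tol:g} "
            "(system uncontrollable with these inputs)")
    lhs = float(np.sum(1.0 / lam))
    rhs = float(n * n / np.sum(lam))
    return lhs, rhs, bool(lhs >= rhs * (1 - 1e-12))
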