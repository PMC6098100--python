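"""Markov-Shannon entropy centralities.

The structural descriptor at the heart of the package: put a random walker on
a graph, let it take ``k`` steps, and measure how much of the walk probability
mass each node captures.  Formally, with ``A`` the adjacency matrix, the
one-step transition matrix is the degree-normalized ``Pi`` with entries
``p_ij = w_ij / sum_m w_im``, the walk distribution after ``k`` steps is
``kP = 0P @ Pi^k`` from an initial distribution ``0P``, and the order-``k``
Shannon entropy contribution of node ``j`` is ``Sh_kj = -kp_j * log(kp_j)``
(with ``0 log 0 := 0``).  Summing over nodes gives the graph entropy
``Sh_k(G)``, bounded by ``log n`` with equality iff the walk distribution is
uniform; dividing by ``n`` gives the mean node entropy used to describe whole
neural-network topologies.

Conventions (see docs/methods.md): the initial distribution is uniform
``1/n``; logs are base 2 (bits) by default; ``k`` ranges over 0..5; rows of
isolated nodes get a self-loop (``p_ii = 1``) so the chain stays stochastic
without dropping nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graphio import Network

__all__ = [
    "MarkovChainModel",
    "NodeEntropyProfile",
    "markov_matrix",
    "walk_distribution",
    "node_entropies",
    "graph_entropy",
    "mean_node_entropy",
    "entropy_table",
    "K_MAX_DEFAULT",
]

K_MAX_DEFAULT = 5
_STOCHASTIC_TOL = 1e-12


@dataclass
class MarkovChainModel:
    """Row-stochastic walk model on a network.

    ``transition`` is the one-step matrix ``Pi`` (entries ``p_ij``),
    ``initial`` the starting distribution ``0p``.
    """

    transition: np.ndarray
    initial: np.ndarray
    k_max: int = K_MAX_DEFAULT

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        n = self.transition.shape[0]
        if self.transition.shape != (n, n) or self.initial.shape != (n,):
            raise ValueError("transition must be (n, n) and initial (n,)")
        if np.any(self.transition < 0) or np.any(self.initial < 0):
            raise ValueError("probabilities must be nonnegative")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=_STOCHASTIC_TOL):
            raise ValueError("transition rows must sum to 1")
        if abs(self.initial.sum() - 1.0) > _STOCHASTIC_TOL:
            raise ValueError("initial distribution must sum to 1")

    @property
    def n(self) -> int:
        return self.transition.shape[0]


@dataclass
class NodeEntropyProfile:
    """Per-node entropy centralities ``Sh_kj`` for k = 0..k_max (bits by default)."""

    node_id: object
    sh: np.ndarray

    def __post_init__(self) -> None:
        self.sh = np.asarray(self.sh, dtype=float)
        if np.any(~np.isfinite(self.sh)) or np.any(self.sh < 0):
            raise ValueError("entropy values must be finite and nonnegative")


def markov_matrix(net: Network, use_weights: bool = True) -> MarkovChainModel:
    """Degree-normalized transition matrix with a uniform initial distribution.

    Isolated nodes get ``p_ii = 1`` so the matrix stays row-stochastic and the
    node count of the web is preserved.
    """
    if net.n < 1:
        raise ValueError("network must have at least one node")
    a = net.adjacency if use_weights else (net.adjacency > 0).astype(float)
    if a.min(initial=0.0) < 0:
        raise ValueError("negative weights are not allowed")
    deg = a.sum(axis=1)
    trans = np.zeros_like(a)
    pos = deg > 0
    trans[pos] = a[pos] / deg[pos, None]
    iso = np.flatnonzero(~pos)
    trans[iso, iso] = 1.0
    initial = np.full(net.n, 1.0 / net.n)
    return MarkovChainModel(trans, initial)


def walk_distribution(model: MarkovChainModel, k: int) -> np.ndarray:
    """Node-occupancy distribution after a ``k``-step walk: ``initial @ Pi^k``."""
    if k < 0:
        raise ValueError("walk length k must be nonnegative")
    if k > model.k_max:
        raise ValueError(f"k={k} exceeds k_max={model.k_max}")
    p = model.initial.copy()
    for _ in range(k):
        p = p @ model.transition
    return p


def _plogp(p: np.ndarray, log_base: float) -> np.ndarray:
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = -p[pos] * np.log(p[pos]) / np.log(log_base)
    return out


def node_entropies(
    net: Network,
    k_max: int = K_MAX_DEFAULT,
    log_base: float = 2.0,
    use_weights: bool = True,
    per_row: bool = False,
) -> list[NodeEntropyProfile]:
    """Entropy profile ``Sh_kj`` of every node, for k = 0..k_max.

    The default reading takes node ``j``'s entropy as its contribution term
    ``-kp_j log kp_j`` inside the graph entropy, so the graph entropy
    decomposes exactly as the sum of node entropies.  ``per_row=True``
    switches to an alternative reading — the full Shannon entropy of row
    ``j`` of ``Pi^k`` (where the walker starting at ``j`` ends up) — kept for
    comparison, not the default.
    """
    model = markov_matrix(net, use_weights=use_weights)
    model.k_max = max(k_max, model.k_max)
    sh = np.empty((net.n, k_max + 1))
    if per_row:
        power = np.eye(net.n)
        for k in range(k_max + 1):
            sh[:, k] = _plogp(power, log_base).sum(axis=1)
            power = power @ model.transition
    else:
        p = model.initial.copy()
        for k in range(k_max + 1):
            sh[:, k] = _plogp(p, log_base)
            p = p @ model.transition
    return [NodeEntropyProfile(lab, sh[i]) for i, lab in enumerate(net.node_ids)]


def graph_entropy(
    net: Network, k: int, log_base: float = 2.0, use_weights: bool = True
) -> float:
    """Graph entropy ``Sh_k(G) = sum_j Sh_kj``; lies in ``[0, log n]``."""
    model = markov_matrix(net, use_weights=use_weights)
    model.k_max = max(k, model.k_max)
    p = walk_distribution(model, k)
    return float(_plogp(p, log_base).sum())


def mean_node_entropy(
    net: Network, k: int, log_base: float = 2.0, use_weights: bool = True
) -> float:
    """Average node entropy ``Sh_k(G) / n`` — the whole-graph descriptor."""
    return graph_entropy(net, k, log_base=log_base, use_weights=use_weights) / net.n


def entropy_table(
    net: Network,
    k_max: int = K_MAX_DEFAULT,
    log_base: float = 2.0,
    use_weights: bool = True,
) -> pd.DataFrame:
    """Tidy descriptor table: one row per node, columns node_id, Sh_0..Sh_k_max."""
    profiles = node_entropies(net, k_max=k_max, log_base=log_base, use_weights=use_weights)
    return pd.DataFrame(
        {
            "node_id": [p.node_id for p in profiles],
            **{f"Sh_{k}": [p.sh[k] for p in profiles] for k in range(k_max + 1)},
        }
    )
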