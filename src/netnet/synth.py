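"""Synthetic bipartite interaction webs.

Real interaction webs (plant-pollinator, host-parasite) are bipartite, sparse
(connectance typically 0.05-0.3) and degree-skewed: a few generalist species
hold most links.  The generator emulates those three properties and nothing
else: link probability for species pair (i, j) is proportional to u_i * v_j
with log-normal propensities u, v whose log-sd is the ``heterogeneity``
parameter (0 recovers a bipartite Erdos-Renyi web), scaled to hit the target
connectance, resampling until no species is isolated.  It exists so the whole
pipeline is testable without any external download; it does not replicate
any specific empirical web, nor nestedness/modularity structure beyond what
degree skew induces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .entropy import entropy_table
from .graphio import Network

__all__ = [
    "SynthConfig",
    "InfeasibleConfigError",
    "generate_bipartite_ben",
    "generate_web_collection",
    "make_fixture_suite",
    "fixture_descriptor_table",
]

_RETRY_CAP = 200


class InfeasibleConfigError(RuntimeError):
    """Raised when the no-isolated-species constraint cannot be met."""


@dataclass
class SynthConfig:
    """Knobs of one synthetic web.

    n_rows / n_cols: species counts per guild (e.g. plants / pollinators).
    connectance: expected fraction of realized links, in (0, 1).
    heterogeneity: log-sd of the species propensities; 0 = homogeneous.
    """

    n_rows: int
    n_cols: int
    connectance: float
    heterogeneity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("need at least one species per guild")
        if not 0.0 < self.connectance < 1.0:
            raise ValueError("connectance must lie in (0, 1)")
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity must be >= 0")
        if self.n_rows * self.n_cols * self.connectance < 1.0:
            raise ValueError("expected link count below 1; raise connectance or size")


def generate_bipartite_ben(cfg: SynthConfig) -> Network:
    """Draw one bipartite web; byte-identical under the same config."""
    rng = np.random.default_rng(cfg.seed)
    nr, nc = cfg.n_rows, cfg.n_cols
    for _ in range(_RETRY_CAP):
        u = rng.lognormal(0.0, cfg.heterogeneity, nr) if cfg.heterogeneity else np.ones(nr)
        v = rng.lognormal(0.0, cfg.heterogeneity, nc) if cfg.heterogeneity else np.ones(nc)
        p = np.outer(u, v)
        p *= cfg.connectance / p.mean()
        p = np.clip(p, 0.0, 1.0)
        block = (rng.random((nr, nc)) < p).astype(float)
        if block.sum(axis=1).min() > 0 and block.sum(axis=0).min() > 0:
            rows = [f"R{i + 1}" for i in range(nr)]
            cols = [f"C{j + 1}" for j in range(nc)]
            n = nr + nc
            adj = np.zeros((n, n))
            adj[:nr, nr:] = block
            adj[nr:, :nr] = block.T
            return Network(
                rows + cols, adj, bipartite_partition=(rows, cols)
            )
    raise InfeasibleConfigError(
        f"could not avoid isolated species in {_RETRY_CAP} draws "
        f"({nr}x{nc}, connectance {cfg.connectance})"
    )


def generate_web_collection(
    n_webs: int,
    seed: int = 0,
    n_rows: int = 12,
    n_cols: int = 12,
    connectance: float = 0.25,
    heterogeneity: float = 0.4,
    size_jitter: float = 0.3,
) -> list[Network]:
    """A collection of webs with varied sizes, standing in for a web archive.

    Sizes per guild vary uniformly by ``+/- size_jitter`` around the nominal
    counts; connectance and heterogeneity are shared.  The defaults are in
    the range reported for empirical interaction webs — a dozen-odd species
    per guild, connectance around 0.25, moderate generalist/specialist skew —
    while staying comfortably inside the feasibility region of the
    no-isolated-species constraint.
    """
    rng = np.random.default_rng(seed)
    webs = []
    for w in range(n_webs):
        jr = int(round(n_rows * (1 + rng.uniform(-size_jitter, size_jitter))))
        jc = int(round(n_cols * (1 + rng.uniform(-size_jitter, size_jitter))))
        cfg = SynthConfig(
            n_rows=max(jr, 3),
            n_cols=max(jc, 3),
            connectance=connectance,
            heterogeneity=heterogeneity,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        webs.append(generate_bipartite_ben(cfg))
    return webs


def make_fixture_suite(seed: int = 0) -> dict[str, Network]:
    """Deterministic small suite for regression tests.

    Path, star, triangle, K_{2,2} and two random bipartite webs; the same
    seed reproduces the suite exactly.
    """
    path = Network(["a", "b", "c"], np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float))
    star_adj = np.zeros((5, 5))
    star_adj[0, 1:] = star_adj[1:, 0] = 1.0
    star = Network(["hub", "s1", "s2", "s3", "s4"], star_adj)
    k3 = Network(["x", "y", "z"], np.ones((3, 3)) - np.eye(3))
    k22_adj = np.zeros((4, 4))
    k22_adj[:2, 2:] = k22_adj[2:, :2] = 1.0
    k22 = Network(
        ["p1", "p2", "q1", "q2"], k22_adj, bipartite_partition=(["p1", "p2"], ["q1", "q2"])
    )
    web_a = generate_bipartite_ben(
        SynthConfig(8, 6, connectance=0.3, heterogeneity=0.5, seed=seed + 11)
    )
    web_b = generate_bipartite_ben(
        SynthConfig(10, 10, connectance=0.2, heterogeneity=0.0, seed=seed + 23)
    )
    return {
        "path3": path,
        "star5": star,
        "k3": k3,
        "k22": k22,
        "web_a": web_a,
        "web_b": web_b,
    }


def fixture_descriptor_table(suite: dict[str, Network]) -> pd.DataFrame:
    """Entropy descriptors of every fixture node, one tidy frame."""
    frames = []
    for name, net in suite.items():
        t = entropy_table(net)
        t.insert(0, "network", name)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
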