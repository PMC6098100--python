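"""Neural-network topologies as graphs.

A feed-forward classifier is itself a network: neurons are nodes and weights
are links.  That makes the same Markov-Shannon entropy machinery applicable to
the classifier as to the ecosystem it predicts — the whole-topology descriptor
``annSh_k`` is simply the mean node entropy of the layered graph.

Two notations are parsed:

* the Statistica-style full form ``"MLP 18:18-8-13-1:1"`` — the numbers
  between the colons are the complete layer list (input through output); the
  ``in:`` prefix and ``:out`` suffix are redundant annotations of the first
  and last layer size and must agree with them;
* the hidden-layer form ``"n-n*2-n"`` used for deep fully-connected nets,
  where ``n`` is substituted (``n*2`` doubles, ``n:2``/``n:4`` floor-divide)
  and the input/output layer sizes are supplied separately.

A registry of ten reference topologies (seven MLPs with one or two hidden
layers, three linear networks) ships with the package together with their
descriptor values as printed by the MI-NODES tool.  Those printed values
follow an initial-probability convention MI-NODES does not document, so they
are carried as fixtures and never recomputed; this package's own convention
(uniform initial distribution, base-2 logs) is available for any topology via
:func:`ann_descriptors`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .entropy import K_MAX_DEFAULT, mean_node_entropy
from .graphio import Network

__all__ = [
    "AnnTopology",
    "parse_topology",
    "topology_graph",
    "ann_descriptors",
    "reference_registry",
]

_FULL_RE = re.compile(r"^\s*(?:(MLP|LNN|FC)\s*)?(\d+):(\d+(?:-\d+)*):(\d+)\s*$")
_HIDDEN_TOKEN_RE = re.compile(r"^(\d+|n|n\*2|n:2|n:4)$")


@dataclass
class AnnTopology:
    """Parsed layer structure of a feed-forward classifier.

    ``layer_sizes`` runs input layer through output layer.  ``descriptors``
    (the 6-vector ``annSh_0..annSh_5``) is computed lazily from the layered
    graph under this package's entropy convention; ``printed_descriptors``,
    when present, holds the registry's fixture values from the MI-NODES tool.
    """

    name: str
    kind: str
    layer_sizes: list[int]
    printed_descriptors: Optional[np.ndarray] = None
    auroc: Optional[float] = None
    _descriptors: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 2:
            raise ValueError("a topology needs at least an input and an output layer")
        if any(s <= 0 for s in self.layer_sizes):
            raise ValueError("zero- or negative-size layer")
        if self.kind not in ("MLP", "LNN", "FC"):
            raise ValueError(f"unknown topology kind {self.kind!r}")
        if self.printed_descriptors is not None:
            self.printed_descriptors = np.asarray(self.printed_descriptors, dtype=float)
            if self.printed_descriptors.shape != (K_MAX_DEFAULT + 1,):
                raise ValueError("printed descriptor vector must have 6 entries")

    @property
    def n_nodes(self) -> int:
        return sum(self.layer_sizes)

    @property
    def hidden_sizes(self) -> tuple[int, ...]:
        return tuple(self.layer_sizes[1:-1])

    @property
    def descriptors(self) -> np.ndarray:
        if self._descriptors is None:
            self._descriptors = ann_descriptors(self)
        return self._descriptors


def parse_topology(
    spec: str,
    input_size: Optional[int] = None,
    output_size: int = 1,
    n: Optional[int] = None,
) -> AnnTopology:
    """Parse a topology string in either full or hidden-layer notation.

    >>> parse_topology("MLP 18:18-8-13-1:1").layer_sizes
    [18, 8, 13, 1]
    >>> parse_topology("n-n*2-n", input_size=18, n=200).layer_sizes
    [18, 200, 400, 200, 1]
    """
    m = _FULL_RE.match(spec)
    if m is not None:
        kind, prefix, body, suffix = m.groups()
        layers = [int(x) for x in body.split("-")]
        if int(prefix) != layers[0]:
            raise ValueError(
                f"input annotation {prefix} disagrees with first layer {layers[0]}"
            )
        if int(suffix) != layers[-1]:
            raise ValueError(
                f"output annotation {suffix} disagrees with last layer {layers[-1]}"
            )
        if kind is None:
            kind = "LNN" if len(layers) == 2 else "MLP"
        if kind == "LNN" and len(layers) != 2:
            raise ValueError("LNN topologies have no hidden layer")
        name = f"{kind} {prefix}:{body}:{suffix}"
        topo = AnnTopology(name=name, kind=kind, layer_sizes=layers)
    else:
        if input_size is None:
            raise ValueError(
                f"cannot parse {spec!r} as full notation; hidden-layer notation "
                "requires input_size (and n when the spec uses 'n')"
            )
        hidden = []
        for token in spec.strip().split("-"):
            if not _HIDDEN_TOKEN_RE.match(token):
                raise ValueError(f"unparseable layer token {token!r}")
            if token.isdigit():
                hidden.append(int(token))
                continue
            if n is None:
                raise ValueError(f"token {token!r} requires n")
            hidden.append({"n": n, "n*2": n * 2, "n:2": n // 2, "n:4": n // 4}[token])
        layers = [input_size, *hidden, output_size]
        if any(s <= 0 for s in layers):
            raise ValueError("zero-size layer after substitution")
        topo = AnnTopology(name=f"FC {spec.strip()} (n={n})", kind="FC", layer_sizes=layers)
    return topo


def topology_graph(topology: AnnTopology) -> Network:
    """Undirected, unweighted layered graph of the topology.

    Consecutive layers are completely bipartitely connected; there are no
    bias nodes, no skip connections and no intra-layer edges.  Feed-forward
    direction is dropped: the walk-based descriptors act on symmetric
    adjacency.
    """
    sizes = topology.layer_sizes
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    n = int(offsets[-1])
    adj = np.zeros((n, n))
    for layer in range(len(sizes) - 1):
        a0, a1 = offsets[layer], offsets[layer + 1]
        b0, b1 = offsets[layer + 1], offsets[layer + 2]
        adj[a0:a1, b0:b1] = 1.0
        adj[b0:b1, a0:a1] = 1.0
    labels = [
        f"L{layer}N{i}"
        for layer, size in enumerate(sizes)
        for i in range(size)
    ]
    return Network(labels, adj)


def ann_descriptors(topology: AnnTopology, log_base: float = 2.0) -> np.ndarray:
    """Whole-topology descriptor vector: mean node entropy at each k = 0..5."""
    graph = topology_graph(topology)
    return np.array(
        [mean_node_entropy(graph, k, log_base=log_base) for k in range(K_MAX_DEFAULT + 1)]
    )


def reference_registry() -> list[AnnTopology]:
    """The ten reference topologies with their printed MI-NODES descriptors.

    The loader asserts the registry's structural pattern: for the three linear
    (LNN) entries the printed descriptor is constant for every k >= 1.
    """
    with resources.files("netnet.data").joinpath("topology_registry.csv").open() as fh:
        table = pd.read_csv(fh)
    registry = []
    for row in table.itertuples(index=False):
        topo = parse_topology(row.topology)
        topo.printed_descriptors = np.array(
            [row.sh0, row.sh1, row.sh2, row.sh3, row.sh4, row.sh5]
        )
        topo.auroc = float(row.auroc)
        if topo.kind == "LNN":
            tail = topo.printed_descriptors[1:]
            if not np.all(tail == tail[0]):
                raise ValueError(
                    f"registry corrupted: LNN row {row.no} should have a "
                    "constant descriptor for k >= 1"
                )
        registry.append(topo)
    if len(registry) != 10:
        raise ValueError(f"registry must have 10 topologies, found {len(registry)}")
    return registry
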