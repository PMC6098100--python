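"""Network container and Pajek / edge-list I/O.

Ecological interaction webs (plant-pollinator, host-parasite, food webs) are
commonly distributed as Pajek ``.net`` files: a ``*Vertices N`` section with
1-based vertex ids and optional quoted labels, followed by ``*Edges``
(undirected) and/or ``*Arcs`` (directed) sections.  This module reads and
writes that dialect and exposes the adjacency-matrix representation the rest
of the package consumes.

Internally vertices are 0-based; every public surface speaks node labels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "Network",
    "GraphFormatError",
    "read_pajek",
    "write_pajek",
    "from_edge_list",
    "read_edge_list",
]


class GraphFormatError(ValueError):
    """A malformed network file or edge list; carries the offending line number."""

    def __init__(self, message: str, line_no: Optional[int] = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


@dataclass
class Network:
    """A node/edge structure with an explicit adjacency matrix.

    Parameters
    ----------
    node_ids
        Ordered node labels; position in this list is the internal 0-based index.
    adjacency
        Square ``(n, n)`` matrix of nonnegative edge weights (``A``, entries
        ``A_ij``).  Binary for unweighted webs.
    weighted
        Whether any edge carries a weight other than 0/1.
    directed
        If False (the default for ecosystem webs, where a trophic interaction
        is simply present or absent) the adjacency must be symmetric.
    bipartite_partition
        Optional pair of disjoint label sets (e.g. plants | pollinators).
        When present every edge must cross the partition.
    """

    node_ids: list
    adjacency: np.ndarray
    weighted: bool = False
    directed: bool = False
    bipartite_partition: Optional[tuple] = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n = len(self.node_ids)
        if len(set(self.node_ids)) != n:
            raise ValueError("duplicate node labels")
        if self.adjacency.shape != (n, n):
            raise ValueError(
                f"adjacency shape {self.adjacency.shape} does not match "
                f"{n} node labels"
            )
        if n and self.adjacency.min(initial=0.0) < 0:
            raise ValueError("negative edge weight in adjacency")
        if n and np.any(np.diagonal(self.adjacency) != 0):
            raise ValueError("self-loops are not allowed")
        if not self.directed and not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("undirected network requires a symmetric adjacency")
        if self.bipartite_partition is not None:
            a, b = (set(self.bipartite_partition[0]), set(self.bipartite_partition[1]))
            if a & b:
                raise ValueError("bipartite partition sets overlap")
            if a | b != set(self.node_ids):
                raise ValueError("bipartite partition must cover all nodes")
            idx = {lab: i for i, lab in enumerate(self.node_ids)}
            ia = sorted(idx[x] for x in a)
            ib = sorted(idx[x] for x in b)
            if np.any(self.adjacency[np.ix_(ia, ia)]) or np.any(
                self.adjacency[np.ix_(ib, ib)]
            ):
                raise ValueError("edges must cross the bipartite partition")

    # -- basic accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        nz = int(np.count_nonzero(self.adjacency))
        return nz if self.directed else nz // 2

    def index(self, label: Hashable) -> int:
        return self.node_ids.index(label)

    def degree(self) -> np.ndarray:
        """Weighted degree (row sums of the adjacency)."""
        return self.adjacency.sum(axis=1)

    def edges(self) -> Iterator[tuple]:
        """Yield ``(label_u, label_v, weight)``; one orientation per undirected edge."""
        rows, cols = np.nonzero(self.adjacency)
        for i, j in zip(rows, cols):
            if not self.directed and j < i:
                continue
            yield self.node_ids[i], self.node_ids[j], float(self.adjacency[i, j])

    def edge_multiset(self) -> set:
        """Label-pair set, orientation-normalized for undirected graphs."""
        out = set()
        for u, v, w in self.edges():
            key = (u, v) if self.directed else tuple(sorted((str(u), str(v))))
            out.add((key, w))
        return out


# ---------------------------------------------------------------------------
# Pajek
# ---------------------------------------------------------------------------

_VERTEX_RE = re.compile(r'^\s*(\d+)(?:\s+"([^"]*)"|\s+(\S+))?(?:\s+.*)?$')


def read_pajek(
    path,
    undirected: bool = True,
    keep_weights: bool = True,
) -> Network:
    """Read a Pajek ``.net`` file.

    ``*Edges`` lines produce symmetric entries.  ``*Arcs`` lines are directed;
    with ``undirected=True`` (the ecosystem default) they are symmetrized by
    the maximum of the two orientations.  A third numeric column on an edge
    line is the weight (otherwise 1); ``keep_weights=False`` binarizes.
    Comment lines starting with ``%`` and coordinates after vertex labels are
    skipped.

    Raises
    ------
    GraphFormatError
        On a malformed vertex count, an edge referencing an unknown vertex id,
        a negative weight or a self-loop, naming the offending line.
    """
    text = Path(path).read_text()
    n = None
    labels: dict[int, str] = {}
    directed_adj = None
    section = None

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("*vertices"):
            parts = line.split()
            if len(parts) < 2 or not parts[1].isdigit():
                raise GraphFormatError("malformed *Vertices count", line_no)
            n = int(parts[1])
            directed_adj = np.zeros((n, n))
            section = "vertices"
            continue
        if low.startswith("*edges"):
            section = "edges"
            continue
        if low.startswith("*arcs"):
            section = "arcs"
            continue
        if line.startswith("*"):
            raise GraphFormatError(f"unknown section {line.split()[0]!r}", line_no)

        if section == "vertices":
            m = _VERTEX_RE.match(line)
            if m is None:
                raise GraphFormatError("malformed vertex line", line_no)
            vid = int(m.group(1))
            if n is None or not (1 <= vid <= n):
                raise GraphFormatError(f"vertex id {vid} outside 1..{n}", line_no)
            labels[vid] = m.group(2) if m.group(2) is not None else (m.group(3) or f"v{vid}")
        elif section in ("edges", "arcs"):
            parts = line.split()
            if len(parts) < 2:
                raise GraphFormatError("edge line needs two vertex ids", line_no)
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise GraphFormatError("non-integer vertex id", line_no) from exc
            w = 1.0
            if len(parts) >= 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise GraphFormatError("non-numeric edge weight", line_no) from exc
            if n is None:
                raise GraphFormatError("edge before *Vertices section", line_no)
            if not (1 <= u <= n and 1 <= v <= n):
                raise GraphFormatError(
                    f"edge ({u}, {v}) references a vertex outside 1..{n}", line_no
                )
            if w < 0:
                raise GraphFormatError(f"negative weight {w}", line_no)
            if u == v:
                raise GraphFormatError(f"self-loop on vertex {u}", line_no)
            i, j = u - 1, v - 1
            directed_adj[i, j] = max(directed_adj[i, j], w)
            if section == "edges":
                directed_adj[j, i] = max(directed_adj[j, i], w)
        else:
            raise GraphFormatError("content before *Vertices section", line_no)

    if n is None:
        raise GraphFormatError("no *Vertices section found")

    adj = directed_adj
    if undirected:
        adj = np.maximum(adj, adj.T)
    if not keep_weights:
        adj = (adj > 0).astype(float)
    node_ids = [labels.get(i, f"v{i}") for i in range(1, n + 1)]
    weighted = bool(np.any((adj != 0) & (adj != 1)))
    return Network(node_ids, adj, weighted=weighted, directed=not undirected)


def write_pajek(net: Network, path) -> None:
    """Write ``net`` in Pajek format; ``read_pajek`` round-trips the adjacency."""
    lines = [f"*Vertices {net.n}"]
    for i, lab in enumerate(net.node_ids, start=1):
        lines.append(f'{i} "{lab}"')
    idx = {lab: i + 1 for i, lab in enumerate(net.node_ids)}
    lines.append("*Arcs" if net.directed else "*Edges")
    for u, v, w in net.edges():
        if net.weighted:
            lines.append(f"{idx[u]} {idx[v]} {w:g}")
        else:
            lines.append(f"{idx[u]} {idx[v]}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------

def from_edge_list(
    pairs: Iterable[Sequence],
    bipartite: bool = False,
    partition: Optional[tuple] = None,
) -> Network:
    """Build an undirected :class:`Network` from ``(u, v)`` / ``(u, v, weight)`` tuples.

    Node order is first-appearance order.  With ``bipartite=True``, either pass
    ``partition=(group_a, group_b)`` explicitly or let the groups be inferred
    as {first elements} | {second elements} of the pairs.
    """
    node_ids: list = []
    seen = {}
    edges = []
    firsts, seconds = [], []
    for pair in pairs:
        if len(pair) == 2:
            u, v = pair
            w = 1.0
        else:
            u, v, w = pair[0], pair[1], float(pair[2])
        if u == v:
            raise GraphFormatError(f"self-loop rejected: ({u!r}, {u!r})")
        if w < 0:
            raise GraphFormatError(f"negative weight {w} on edge ({u!r}, {v!r})")
        for lab in (u, v):
            if lab not in seen:
                seen[lab] = len(node_ids)
                node_ids.append(lab)
        firsts.append(u)
        seconds.append(v)
        edges.append((u, v, w))

    n = len(node_ids)
    adj = np.zeros((n, n))
    for u, v, w in edges:
        i, j = seen[u], seen[v]
        prev = adj[i, j]
        if prev != 0 and prev != w:
            raise GraphFormatError(
                f"contradictory duplicate weights for edge ({u!r}, {v!r}): {prev} vs {w}"
            )
        adj[i, j] = adj[j, i] = w

    part = None
    if bipartite:
        if partition is None:
            a, b = set(firsts), set(seconds)
            if a & b:
                raise GraphFormatError(
                    "cannot infer bipartite partition: some labels appear on both sides"
                )
            partition = (a, b)
        part = (list(partition[0]), list(partition[1]))
    weighted = any(w != 1.0 for _, _, w in edges)
    return Network(node_ids, adj, weighted=weighted, bipartite_partition=part)


def read_edge_list(path, bipartite: bool = False) -> Network:
    """Read a 2-3 column tab- or comma-separated edge list."""
    pairs = []
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("%", "#")):
            continue
        parts = re.split(r"[,\t]+|\s+", line)
        if len(parts) < 2 or len(parts) > 3:
            raise GraphFormatError("expected 2 or 3 columns", line_no)
        if len(parts) == 3:
            try:
                parts[2] = float(parts[2])
            except ValueError as exc:
                raise GraphFormatError("non-numeric weight column", line_no) from exc
        pairs.append(tuple(parts))
    return from_edge_list(pairs, bipartite=bipartite)
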