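"""Graph and dataset data model for microcircuit analysis.

A *microcircuit* is an undirected weighted graph whose vertices are neurons
(identified by a fixed 1-based index shared across a whole dataset) and whose
edge weights quantify pairwise synchrony, typically a Spearman correlation
between the two neurons' activity traces.  A *microcircuit dataset* is an
indexed collection of such graphs over one common vertex set, optionally
paired with binary labels for downstream classification.

Datasets are serialized in a small plain-text edge-list dialect::

    k n_G
    graph 0 [label]
    u v [w]
    ...
    graph 1 [label]
    ...

The header gives the common vertex count ``k`` and the number of graphs
``n_G``.  Vertex indices in edge lines are 1-based.  The weight column is
present exactly when the dataset is weighted; labels, when present, must be
given for every graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable


class ParseError(ValueError):
    """Malformed dataset file; message carries the 1-based line number."""


def _normalize_edge(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class UnweightedGraph:
    """Undirected simple graph on the vertex set {1, ..., vertex_count}.

    Vertex indices double as vertex *identifiers*: ID(v_i) = i.  Edges are
    stored as sorted pairs (u, v) with u < v; self-loops and duplicate edges
    are rejected.
    """

    vertex_count: int
    edges: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.vertex_count < 1:
            raise ValueError(f"vertex_count must be positive, got {self.vertex_count}")
        normalized = set()
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on vertex {u} is not allowed")
            e = _normalize_edge(u, v)
            if not (1 <= e[0] <= self.vertex_count and 1 <= e[1] <= self.vertex_count):
                raise ValueError(f"edge {e} has an endpoint outside 1..{self.vertex_count}")
            normalized.add(e)
        object.__setattr__(self, "edges", frozenset(normalized))

    @classmethod
    def from_edges(cls, vertex_count: int, edges: Iterable[tuple[int, int]]) -> "UnweightedGraph":
        edge_list = [_normalize_edge(u, v) for u, v in edges]
        if len(edge_list) != len(set(edge_list)):
            raise ValueError("duplicate edges are not allowed")
        return cls(vertex_count, frozenset(edge_list))

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def degree(self, v: int) -> int:
        """Number of edges incident to vertex ``v`` (1-based)."""
        if not (1 <= v <= self.vertex_count):
            raise IndexError(f"vertex index {v} outside 1..{self.vertex_count}")
        return sum(1 for e in self.edges if v in e)

    def neighbors(self, v: int) -> list[int]:
        """Sorted neighbor indices of vertex ``v``."""
        if not (1 <= v <= self.vertex_count):
            raise IndexError(f"vertex index {v} outside 1..{self.vertex_count}")
        return sorted(u + w - v for u, w in self.edges if v in (u, w))

    def sorted_edges(self) -> list[tuple[int, int]]:
        return sorted(self.edges)


def degree(g: UnweightedGraph, v: int) -> int:
    """Module-level alias for :meth:`UnweightedGraph.degree`."""
    return g.degree(v)


@dataclass(frozen=True)
class Microcircuit:
    """Weighted undirected graph: a structure plus a weight per edge."""

    graph: UnweightedGraph
    weights: dict[tuple[int, int], float]

    def __post_init__(self) -> None:
        normalized = {_normalize_edge(u, v): float(w) for (u, v), w in self.weights.items()}
        if set(normalized) != set(self.graph.edges):
            raise ValueError("weights must have exactly one entry per edge of the graph")
        object.__setattr__(self, "weights", normalized)

    @property
    def vertex_count(self) -> int:
        return self.graph.vertex_count


@dataclass
class MicrocircuitDataset:
    """Indexed set of graphs over one common vertex set, with optional labels.

    ``members`` may hold :class:`Microcircuit` (weighted) or
    :class:`UnweightedGraph` objects, but not a mixture.
    """

    members: list
    common_vertex_count: int
    labels: list[int] | None = None

    def __post_init__(self) -> None:
        for i, m in enumerate(self.members):
            if m.vertex_count != self.common_vertex_count:
                raise ValueError(
                    f"member {i} has vertex_count {m.vertex_count}, "
                    f"expected {self.common_vertex_count}"
                )
        kinds = {isinstance(m, Microcircuit) for m in self.members}
        if len(kinds) > 1:
            raise ValueError("dataset mixes weighted and unweighted members")
        if self.labels is not None:
            if len(self.labels) != len(self.members):
                raise ValueError("labels must align one-to-one with members")
            if any(l not in (0, 1) for l in self.labels):
                raise ValueError("labels must be binary (0/1)")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def weighted(self) -> bool:
        return bool(self.members) and isinstance(self.members[0], Microcircuit)

    def graphs(self) -> list[UnweightedGraph]:
        """The unweighted structures of all members, in order."""
        return [m.graph if isinstance(m, Microcircuit) else m for m in self.members]


def read_dataset(path: str | Path, weighted: bool) -> MicrocircuitDataset:
    """Parse a dataset from the plain-text edge-list dialect.

    Raises :class:`ParseError` naming the offending 1-based line number on
    malformed input (bad header, out-of-range endpoint, duplicate edge,
    missing/spurious weight column, bad label).
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()

    def fail(lineno: int, msg: str) -> None:
        raise ParseError(f"{path}:{lineno}: {msg}")

    content = [(i + 1, ln.strip()) for i, ln in enumerate(lines) if ln.strip()]
    if not content:
        raise ParseError(f"{path}:1: empty file")

    lineno, header = content[0]
    parts = header.split()
    if len(parts) != 2:
        fail(lineno, f"header must be 'k n_G', got {header!r}")
    try:
        k, n_g = int(parts[0]), int(parts[1])
    except ValueError:
        fail(lineno, f"header must hold two integers, got {header!r}")
    if k < 1 or n_g < 0:
        fail(lineno, f"header values out of range: k={k}, n_G={n_g}")

    members: list = []
    labels: list[int] = []
    have_labels: bool | None = None

    cur_edges: dict[tuple[int, int], float] | None = None
    cur_start = lineno

    def close_graph() -> None:
        nonlocal cur_edges
        if cur_edges is None:
            return
        g = UnweightedGraph(k, frozenset(cur_edges))
        if weighted:
            members.append(Microcircuit(g, dict(cur_edges)))
        else:
            members.append(g)
        cur_edges = None

    for lineno, line in content[1:]:
        tokens = line.split()
        if tokens[0] == "graph":
            close_graph()
            if len(tokens) not in (2, 3):
                fail(lineno, f"graph record must be 'graph <index> [label]', got {line!r}")
            if len(tokens) == 3:
                if have_labels is False:
                    fail(lineno, "label given but earlier graphs had none")
                have_labels = True
                try:
                    lab = int(tokens[2])
                except ValueError:
                    fail(lineno, f"label must be an integer, got {tokens[2]!r}")
                if lab not in (0, 1):
                    fail(lineno, f"label must be 0 or 1, got {lab}")
                labels.append(lab)
            else:
                if have_labels is True:
                    fail(lineno, "missing label; earlier graphs had labels")
                have_labels = False
            cur_edges = {}
            cur_start = lineno
        else:
            if cur_edges is None:
                fail(lineno, "edge line before any 'graph' record")
            want = 3 if weighted else 2
            if len(tokens) != want:
                fail(lineno, f"edge line must have {want} fields, got {line!r}")
            try:
                u, v = int(tokens[0]), int(tokens[1])
            except ValueError:
                fail(lineno, f"edge endpoints must be integers, got {line!r}")
            if u == v:
                fail(lineno, f"self-loop {u} {v}")
            if not (1 <= u <= k and 1 <= v <= k):
                fail(lineno, f"edge ({u},{v}) has an endpoint outside 1..{k}")
            e = _normalize_edge(u, v)
            if e in cur_edges:
                fail(lineno, f"duplicate edge ({u},{v})")
            if weighted:
                try:
                    w = float(tokens[2])
                except ValueError:
                    fail(lineno, f"edge weight must be a number, got {tokens[2]!r}")
            else:
                w = 1.0
            cur_edges[e] = w
    close_graph()

    if len(members) != n_g:
        fail(cur_start, f"header promised {n_g} graphs but file holds {len(members)}")

    return MicrocircuitDataset(
        members=members,
        common_vertex_count=k,
        labels=labels if have_labels else None,
    )


def write_dataset(d: MicrocircuitDataset, path: str | Path) -> None:
    """Serialize a dataset into the edge-list dialect read by :func:`read_dataset`.

    Edges are emitted sorted by (min, max) endpoint; weights are printed with
    17 significant digits so the read-back value equals the original float.
    """
    out: list[str] = [f"{d.common_vertex_count} {len(d)}"]
    for i, m in enumerate(d.members):
        rec = f"graph {i}"
        if d.labels is not None:
            rec += f" {d.labels[i]}"
        out.append(rec)
        if isinstance(m, Microcircuit):
            for e in m.graph.sorted_edges():
                out.append(f"{e[0]} {e[1]} {m.weights[e]:.17g}")
        else:
            for e in m.sorted_edges():
                out.append(f"{e[0]} {e[1]}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")
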