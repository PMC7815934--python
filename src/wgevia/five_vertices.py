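"""The five vertices benchmark: a probe for vertex-identity awareness.

Six template graphs delta_1..delta_6 share the common vertex set
{v_1..v_5}; each template is replicated ``copies_per_subset`` times (500 by
default, 3,000 graphs in total).  Labels are 0 for delta_1/3/5 and 1 for
delta_2/4/6.  The benchmark is deliberately trivial as a *structural*
classification task: the interesting pairs (delta_3 vs delta_4 and delta_5
vs delta_6) are isomorphic and differ only in which vertex IDs carry the
edges, so an embedding that ignores identities cannot beat chance on them,
while delta_1 vs delta_2 differ in edge count and are separable by any
reasonable method.

Default templates:

    delta_1: {1,2}                 delta_2: {1,2},{2,3},{3,4}
    delta_3: {1,2}                 delta_4: {3,4}
    delta_5: {1,2},{2,3}           delta_6: {3,4},{4,5}

delta_3/delta_4 and delta_5/delta_6 are isomorphic pairs on different IDs;
every template leaves several vertices isolated, exercising the special
zero-degree labeling.  Alternative templates with the same abstract
properties can be supplied through :class:`FiveVerticesSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_graphs import MicrocircuitDataset, UnweightedGraph

VERTEX_COUNT = 5

_DEFAULT_EDGES: tuple[tuple[tuple[int, int], ...], ...] = (
    ((1, 2),),
    ((1, 2), (2, 3), (3, 4)),
    ((1, 2),),
    ((3, 4),),
    ((1, 2), (2, 3)),
    ((3, 4), (4, 5)),
)


def default_templates() -> tuple[UnweightedGraph, ...]:
    return tuple(
        UnweightedGraph.from_edges(VERTEX_COUNT, edges) for edges in _DEFAULT_EDGES
    )


@dataclass(frozen=True)
class FiveVerticesSpec:
    """Benchmark parameters: replication count and the six templates."""

    copies_per_subset: int = 500
    structures: tuple[UnweightedGraph, ...] = field(default_factory=default_templates)

    def __post_init__(self) -> None:
        if self.copies_per_subset < 1:
            raise ValueError("copies_per_subset must be >= 1")
        if len(self.structures) != 6:
            raise ValueError("exactly six template graphs are required")
        k = self.structures[0].vertex_count
        if any(g.vertex_count != k for g in self.structures):
            raise ValueError("all templates must share one vertex count")
        d1, d2, d3, d4, d5, d6 = self.structures
        if d1.edge_count == d2.edge_count:
            raise ValueError("delta_1 and delta_2 must differ in edge count")
        for a, b, name in ((d3, d4, "delta_3/delta_4"), (d5, d6, "delta_5/delta_6")):
            if a.edge_count != b.edge_count:
                raise ValueError(f"{name} must have equal edge counts")
            if a.edges == b.edges:
                raise ValueError(f"{name} must place edges on different vertex IDs")

    @property
    def labels(self) -> tuple[int, ...]:
        # subsets 1,3,5 -> class 0; subsets 2,4,6 -> class 1
        return (0, 1, 0, 1, 0, 1)


def generate_five_vertices(spec: FiveVerticesSpec | None = None) -> MicrocircuitDataset:
    """Materialize the benchmark: 6 x copies graphs in subset order, labeled."""
    spec = spec or FiveVerticesSpec()
    members: list[UnweightedGraph] = []
    labels: list[int] = []
    for template, label in zip(spec.structures, spec.labels):
        members.extend([template] * spec.copies_per_subset)
        labels.extend([label] * spec.copies_per_subset)
    return MicrocircuitDataset(
        members=members,
        common_vertex_count=spec.structures[0].vertex_count,
        labels=labels,
    )


def select_experiment(i: int, dataset: MicrocircuitDataset) -> MicrocircuitDataset:
    """Pairwise experiment i in {1,2,3}: subsets delta_{2i-1} and delta_{2i}.

    Experiment 1 tests separation by edge count; experiments 2 and 3 test
    separation of isomorphic structures on different vertex identities.
    """
    if i not in (1, 2, 3):
        raise ValueError(f"experiment index must be 1, 2 or 3, got {i}")
    if len(dataset) % 6 != 0:
        raise ValueError("dataset length is not a multiple of six subsets")
    copies = len(dataset) // 6
    lo = (2 * i - 2) * copies
    hi = 2 * i * copies
    return MicrocircuitDataset(
        members=list(dataset.members[lo:hi]),
        common_vertex_count=dataset.common_vertex_count,
        labels=list(dataset.labels[lo:hi]) if dataset.labels is not None else None,
    )
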