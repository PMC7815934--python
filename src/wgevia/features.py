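"""Identity-aware iterative feature extraction for unweighted graphs.

This is a Weisfeiler-Lehman-style relabeling scheme: in each iteration every
vertex receives a new feature string obtained by hashing the concatenation of
its own current feature with the sorted current features of its neighbors.
Because initial features carry vertex identities (see
:mod:`wgevia.embedding`), two isomorphic graphs whose edges sit on different
vertex IDs yield different feature libraries — the property that makes the
embedding identity-aware.

Zero-degree vertices have no neighbors to draw from, so they instead combine
the features of the vertices immediately preceding and succeeding them in the
vertex ordering, wrapping around (v_k precedes v_1).  This keeps isolated
neurons — common in sparse microcircuit graphs — distinguishable by their
position in the common vertex set.

All hashed features are lowercase hexadecimal MD5 digests (32 characters),
which bounds feature storage regardless of graph size or iteration depth.
"""

from __future__ import annotations

import hashlib
from typing import Sequence

from .core_graphs import UnweightedGraph

#: Delimiter used in every feature concatenation.
DELIM = "_"


def concat(s1: str, s2: str, delim: str = DELIM) -> str:
    """Delimited concatenation: concat("27", "33", "_") == "27_33"."""
    return f"{s1}{delim}{s2}"


def hash_feature(s: str) -> str:
    """Lowercase hex MD5 digest of the UTF-8 bytes of ``s`` (32 chars)."""
    return hashlib.md5(s.encode("utf-8")).hexdigest()


def _edge_count_feature(g: UnweightedGraph) -> str:
    # Graph-level word: lets the downstream document embedding see the total
    # edge count even when all vertex-level features differ.
    return hash_feature("E" + str(g.edge_count))


def extract_features(
    g: UnweightedGraph,
    initial_features: Sequence[str],
    feature_gen_iters: int,
    zero_degree_wraparound: bool = True,
) -> list[str]:
    """Build the feature library of ``g`` from per-vertex initial features.

    The library lists, in order: one edge-count feature for the whole graph,
    the ``k`` initial per-vertex features, then ``k`` new hashed features per
    iteration.  Its length is therefore ``1 + k + feature_gen_iters * k``.

    Within one iteration all vertices read the *previous* iteration's
    features (snapshot semantics), so the result does not depend on the
    sweep order.  A vertex of positive degree hashes
    ``own + "_" + "_".join(sorted(neighbor features))``; a zero-degree vertex
    v_i hashes ``own + "_" + prev + "_" + next`` where prev/next are v_{i-1}
    and v_{i+1} with wrap-around.

    ``zero_degree_wraparound=False`` disables the positional rule: an
    isolated vertex then simply rehashes its own feature.  This matters for
    the identity-agnostic baseline, where positional neighbors would leak
    vertex identities into supposedly identity-blind features.
    """
    if feature_gen_iters < 1:
        raise ValueError(f"feature_gen_iters must be >= 1, got {feature_gen_iters}")
    k = g.vertex_count
    if len(initial_features) != k:
        raise ValueError(
            f"expected {k} initial features, got {len(initial_features)}"
        )

    neighbors = {v: g.neighbors(v) for v in range(1, k + 1)}
    current = [str(f) for f in initial_features]

    library: list[str] = [_edge_count_feature(g)]
    library.extend(current)

    for _ in range(feature_gen_iters):
        new = []
        for i in range(1, k + 1):
            own = current[i - 1]
            nbrs = neighbors[i]
            if nbrs:
                joined = DELIM.join(sorted(current[j - 1] for j in nbrs))
                new.append(hash_feature(concat(own, joined)))
            elif zero_degree_wraparound:
                prev = current[(i - 2) % k]
                succ = current[i % k]
                new.append(hash_feature(concat(own, concat(prev, succ))))
            else:
                new.append(hash_feature(own))
        library.extend(new)
        current = new

    return library
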