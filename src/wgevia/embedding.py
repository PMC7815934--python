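"""UGEVIA: identity-aware graph-level embedding of unweighted graphs.

Pipeline: (1) label every vertex with a string that fuses its degree and its
identity, (2) run the iterative feature extractor to obtain one feature
library (document) per graph, (3) train paragraph vectors over the corpus of
libraries.  The output is one real vector per graph.

Labeling modes
--------------
``identity_aware`` (the default) labels vertex v_i with ``"<degree>_<i>"``;
with ``zero_degree_special`` enabled, isolated vertices get ``"Z<i>"``
instead, which both marks them for the wrap-around neighbor rule in the
feature extractor and keeps their identity in the corpus vocabulary.
``degree_only`` reproduces the identity-agnostic graph2vec-style baseline:
every vertex is labeled with its degree alone, so isomorphic graphs on
different vertex IDs become indistinguishable — by design, as the baseline
against which identity awareness is measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core_graphs import UnweightedGraph
from .docembed import DocEmbedParams, embed_documents
from .features import extract_features

LABELING_MODES = ("identity_aware", "degree_only")


@dataclass(frozen=True)
class EmbeddingConfig:
    """Configuration of one UGEVIA run.

    ``dim`` is the output dimension m (defaults to 8, the per-channel
    dimension used by the multi-channel method); ``feature_gen_iters`` is the
    number of relabeling iterations (default 4).
    """

    dim: int = 8
    feature_gen_iters: int = 4
    labeling_mode: str = "identity_aware"
    zero_degree_special: bool = True
    doc_embed: DocEmbedParams = field(default_factory=DocEmbedParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.labeling_mode not in LABELING_MODES:
            raise ValueError(
                f"labeling_mode must be one of {LABELING_MODES}, got {self.labeling_mode!r}"
            )


#: FeatureCorpus: ordered (graph index, feature library) records.
FeatureCorpus = list[tuple[int, list[str]]]


def initialize_vertex_labels(
    g: UnweightedGraph,
    mode: str = "identity_aware",
    zero_degree_special: bool = True,
) -> list[str]:
    """Initial per-vertex feature strings under the chosen labeling mode."""
    if mode not in LABELING_MODES:
        raise ValueError(f"unknown labeling mode {mode!r}")
    labels = []
    for i in range(1, g.vertex_count + 1):
        d = g.degree(i)
        if mode == "degree_only":
            labels.append(str(d))
        elif d == 0 and zero_degree_special:
            labels.append(f"Z{i}")
        else:
            labels.append(f"{d}_{i}")
    return labels


def build_corpus(
    graphs: Sequence[UnweightedGraph], cfg: EmbeddingConfig
) -> FeatureCorpus:
    """Label vertices and extract one feature library per graph, in order."""
    if not graphs:
        raise ValueError("cannot build a corpus from zero graphs")
    k = graphs[0].vertex_count
    if any(g.vertex_count != k for g in graphs):
        raise ValueError("all graphs must share one common vertex count")
    # The positional zero-degree rule is part of the special handling; the
    # identity-agnostic and no-special-features modes fall back to plain
    # self-rehashing for isolated vertices.
    wraparound = cfg.labeling_mode == "identity_aware" and cfg.zero_degree_special
    corpus: FeatureCorpus = []
    for idx, g in enumerate(graphs):
        init = initialize_vertex_labels(g, cfg.labeling_mode, cfg.zero_degree_special)
        corpus.append(
            (idx, extract_features(g, init, cfg.feature_gen_iters, wraparound))
        )
    return corpus


def embed_corpus(
    corpus: FeatureCorpus,
    dim: int,
    params: DocEmbedParams | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Train paragraph vectors for a corpus; rows follow record order."""
    if not corpus:
        raise ValueError("cannot embed an empty corpus")
    documents = [lib for _, lib in corpus]
    return embed_documents(documents, dim, params, seed)


def ugevia(
    graphs: Sequence[UnweightedGraph], cfg: EmbeddingConfig | None = None
) -> np.ndarray:
    """Embed unweighted graphs sharing a common vertex set; (n_G, dim) array."""
    cfg = cfg or EmbeddingConfig()
    corpus = build_corpus(graphs, cfg)
    return embed_corpus(corpus, cfg.dim, cfg.doc_embed, cfg.seed)


def with_seed(cfg: EmbeddingConfig, seed: int) -> EmbeddingConfig:
    """Copy of ``cfg`` with a different seed (used for per-channel runs)."""
    return replace(cfg, seed=seed)
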