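"""Paragraph-vector (PV-DBOW) document embedding trained with negative sampling.

Feature libraries are treated as bags of word tokens; each document (graph)
owns a trainable vector that is pushed, by stochastic gradient ascent, to
score its own tokens above randomly drawn noise tokens:

    maximize  log sigma(d . w)  +  sum_neg log sigma(-d . w_neg)

This is the distributed bag-of-words paragraph-vector model of Le & Mikolov,
the variant used in the graph2vec lineage.  Documents sharing many tokens end
up with nearby vectors; documents with disjoint token sets are pushed toward
different regions of the space, which is exactly what downstream classifiers
exploit.

Conventions follow the common word2vec/doc2vec practice: noise tokens are
drawn from the unigram distribution raised to the 3/4 power, high-frequency
tokens are randomly subsampled with keep probability
``(sqrt(f/t) + 1) * t/f`` for token frequency ``f`` and downsample threshold
``t``, and the learning rate decays linearly over epochs.  Training is fully
vectorized with numpy and deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class DocEmbedParams:
    """Hyperparameters of the document-embedding step.

    Defaults are the tuned values used throughout the experiments:
    learning rate 0.025, downsampling threshold 1e-4, minimum token count 1,
    100 epochs, 5 negative samples per positive pair.
    """

    learning_rate: float = 0.025
    min_learning_rate: float = 0.0001
    downsample: float = 0.0001
    min_count: int = 1
    epochs: int = 100
    negative: int = 5
    batch_size: int = 256

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.negative < 1:
            raise ValueError("negative must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def embed_documents(
    documents: Sequence[Sequence[str]],
    dim: int,
    params: DocEmbedParams | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Train PV-DBOW vectors for ``documents``; returns an (n_docs, dim) array.

    Tokens with corpus count below ``params.min_count`` are ignored.  The
    result is deterministic for a fixed seed.
    """
    if len(documents) == 0:
        raise ValueError("cannot embed an empty corpus")
    if dim < 1:
        raise ValueError(f"embedding dimension must be >= 1, got {dim}")
    params = params or DocEmbedParams()

    # Vocabulary, in first-appearance order for determinism.
    counts: dict[str, int] = {}
    for doc in documents:
        for tok in doc:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = [t for t, c in counts.items() if c >= params.min_count]
    if not vocab:
        raise ValueError("no token survives the min_count filter")
    tok_id = {t: i for i, t in enumerate(vocab)}
    vcount = np.array([counts[t] for t in vocab], dtype=np.float64)
    total = vcount.sum()

    # Flattened (doc, token) pair list over the whole corpus.
    doc_of: list[int] = []
    tok: list[int] = []
    for d, doc in enumerate(documents):
        for t in doc:
            i = tok_id.get(t)
            if i is not None:
                doc_of.append(d)
                tok.append(i)
    doc_of_arr = np.array(doc_of, dtype=np.int64)
    tok_arr = np.array(tok, dtype=np.int64)
    if tok_arr.size == 0:
        raise ValueError("corpus has no usable tokens")

    # Frequent-token subsampling keep probabilities.
    if params.downsample > 0:
        thresh = params.downsample * total
        keep = (np.sqrt(vcount / thresh) + 1.0) * (thresh / vcount)
        keep = np.minimum(keep, 1.0)
    else:
        keep = np.ones_like(vcount)
    keep_pair = keep[tok_arr]

    # Noise distribution: unigram^0.75.
    noise = vcount**0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    rng = np.random.default_rng(seed)
    n_docs = len(documents)
    D = (rng.random((n_docs, dim)) - 0.5) / dim
    W = np.zeros((len(vocab), dim))

    lr0, lr1 = params.learning_rate, params.min_learning_rate
    for epoch in range(params.epochs):
        frac = epoch / max(1, params.epochs - 1)
        alpha = lr0 - (lr0 - lr1) * frac

        mask = rng.random(keep_pair.shape) < keep_pair
        d_idx = doc_of_arr[mask]
        w_idx = tok_arr[mask]
        n_pairs = d_idx.size
        if n_pairs == 0:
            continue

        order = rng.permutation(n_pairs)
        d_idx = d_idx[order]
        w_idx = w_idx[order]
        neg = np.searchsorted(noise_cdf, rng.random((n_pairs, params.negative)))

        # Shuffled mini-batch SGD: within one small batch the few index
        # collisions accumulate additively, which is a faithful enough
        # approximation of per-sample updates.
        for lo in range(0, n_pairs, params.batch_size):
            dd = d_idx[lo : lo + params.batch_size]
            ww = w_idx[lo : lo + params.batch_size]
            nn = neg[lo : lo + params.batch_size]

            dvec = D[dd]
            wpos = W[ww]
            wneg = W[nn]

            g_pos = 1.0 - _sigmoid(np.einsum("ij,ij->i", dvec, wpos))
            g_neg = -_sigmoid(np.einsum("ij,ikj->ik", dvec, wneg))

            d_grad = g_pos[:, None] * wpos + np.einsum("ik,ikj->ij", g_neg, wneg)
            np.add.at(D, dd, alpha * d_grad)
            np.add.at(W, ww, alpha * g_pos[:, None] * dvec)
            np.add.at(
                W,
                nn.ravel(),
                (alpha * g_neg[:, :, None] * dvec[:, None, :]).reshape(-1, dim),
            )

    if not np.all(np.isfinite(D)):
        raise FloatingPointError("document embedding diverged to non-finite values")
    return D
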