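# Methods

This note documents the models and procedures implemented in `wgevia`, the
conventions chosen where the design was genuinely open, and the limits of
what the synthetic benchmarks can show.

## Problem setting

A functional microcircuit is a group of neurons with synchronized activity,
modeled as an undirected graph: vertices are neurons, and each edge carries a
weight quantifying pairwise synchrony (here, the Spearman rank correlation of
the two neurons' activity over a time window). Two properties distinguish
these graphs from generic graph-classification inputs:

1. **Vertices have identities.** Vertex *i* is the same physical neuron in
   every graph of a dataset. Isomorphic graphs whose edges sit on different
   neurons are *different* observations and must receive distinguishable
   embeddings.
2. **Edges are weighted**, and the weight scale matters: which synchrony
   threshold an edge survives is informative.

The package produces one fixed-length real vector per graph (a graph-level
embedding), evaluated through downstream binary classification.

## Unweighted, identity-aware embedding

The unweighted embedder follows the Weisfeiler-Lehman/graph2vec recipe —
iterative vertex relabeling to build a token document per graph, then a
paragraph-vector model over the document corpus — with identity made explicit:

- **Initial labels** fuse degree and identity: vertex *i* with degree *d*
  is labeled `"d_i"`. Degree-0 vertices get `"Zi"` instead. The fused form
  honors both requirements (degree-based initialization and index labeling)
  with a single token; the `Z` prefix both marks isolated vertices for the
  positional update rule and keeps their identity in the vocabulary.
- **Relabeling.** For `feature_gen_iters` iterations (default 4), each
  vertex of positive degree is relabeled with the MD5 digest of
  `own + "_" + "_".join(sorted(neighbor labels))`. Sorting removes any
  dependence on edge storage order; the underscore-fold is the natural
  n-ary extension of binary delimited concatenation and is the package's
  canonical dialect. All reads within an iteration come from the previous
  iteration's snapshot, so the sweep order is irrelevant.
- **Zero-degree rule.** An isolated vertex *v_i* has no graph neighbors;
  under identity-aware labeling it is relabeled from its positional
  neighbors *v_{i-1}* and *v_{i+1}* in the common vertex ordering
  (wrapping around at the ends), regardless of those vertices' degrees.
  This keeps isolated neurons — the majority in sparse microcircuit graphs —
  distinguishable by identity. In the identity-agnostic baseline mode
  (`degree_only`) and in the no-special-features ablation the positional
  rule is disabled (an isolated vertex rehashes its own label): positional
  neighbors would smuggle identity information into modes whose purpose is
  to lack it.
- **Library layout.** Each graph's document contains, in order: one
  graph-level edge-count word (`MD5("E<edge count>")`), the *k* initial
  labels, and *k* new digests per iteration — `1 + k + iters*k` tokens.
  Including the initial labels preserves iteration-0 information; the
  edge-count word gives the document model direct access to overall density.
- **Hashing.** MD5, lowercase hex, UTF-8 input; 32 characters regardless of
  input length, bounding feature storage at any iteration depth.

### Document embedding

Documents are embedded with a PV-DBOW paragraph-vector model implemented in
numpy: each document owns a trainable vector optimized by negative-sampling
SGD to score its tokens above noise tokens drawn from the unigram^0.75
distribution. Hyperparameters: learning rate 0.025 decaying linearly to
0.0001, frequent-token downsampling threshold 1e-4, minimum token count 1,
100 epochs, 5 negative samples. Training is shuffled mini-batch SGD
(batch 256); within a batch the rare index collisions accumulate additively,
a faithful approximation of per-sample updates at a fraction of the Python
overhead. Initialization is uniform in ±0.5/m for document vectors and zero
for token output vectors. A single `numpy` RNG seeded from the run seed makes
training bit-reproducible.

Feature order within a document is not used (bag-of-words); digest tokens
are effectively unique identifiers of rooted neighborhood-plus-identity
structures, so two graphs share a token exactly when they share such a
structure.

## Multi-channel weighted embedding

A weighted dataset is decomposed into `nc` unweighted channels with the
uniform threshold ladder

    T_j = wmax/(2 nc) + (j-1) * wmax/nc,   j = 1..nc,

where `wmax` is the maximum weight over the *whole* dataset. Channel *j*
keeps the edges with weight strictly greater than `T_j` (the same strict
rule as the single-threshold weighted-to-unweighted conversion used for
unweighted baselines, default χ = 0.196). For weights uniform on [0, 1] and
`nc` = 10 the channels retain 95%, 85%, …, 5% of edges. Each channel is
embedded independently at dimension `mu_c` (per-channel seeds are
`seed + channel index`), and the blocks are concatenated: output dimension
`nc × mu_c` (80 at the defaults nc=10, mu_c=8).

Negative weights — possible for Spearman correlations — fall below every
positive threshold and are therefore invisible to all channels. This is a
known limitation of the positive ladder; datasets where negative synchrony
is meaningful would need a ladder over (w_min, w_max), which is out of scope.

## The five vertices benchmark

Six templates on the common vertex set {v_1..v_5}, each replicated 500
times (3,000 graphs), labels alternating 0/1:

| subset | edges | role |
|---|---|---|
| δ1 | {1,2} | differs from δ2 in edge count |
| δ2 | {1,2},{2,3},{3,4} | |
| δ3 | {1,2} | isomorphic to δ4, different IDs |
| δ4 | {3,4} | |
| δ5 | {1,2},{2,3} | isomorphic to δ6, different IDs |
| δ6 | {3,4},{4,5} | |

Only the templates' abstract properties are prescribed (isomorphic pairs on
different identities; an edge-count difference for the first pair; isolated
vertices present); the concrete edge sets above are this package's choice
and are configurable. The replication count exists solely to give the
downstream classifiers enough training instances. Experiments pair
δ_{2i-1} with δ_{2i}; experiment 1 is solvable without identity awareness,
experiments 2 and 3 are not.

## Integrate-and-fire simulator

The two-condition generator emulates an ensemble recording in which a
stimulus-driven population (group A, 50 neurons) drives a downstream
population (group B, 50 neurons) with condition-dependent wiring density:
each B neuron draws 1–2 parents from A in condition 1 and 3–4 in
condition 2. Membrane potentials follow

    d rho/dt = (rho_rest - rho)/tau + sigma * tau^(-1/2) * eps,

Euler-integrated at dt = 1 with eps ~ N(0,1). Crossing the spike threshold
(strictly) resets the potential to rest and silences the neuron for the
refractory period; synaptic events arrive with one step of delay.

Constants not fixed by the model statement are defaults of this package:
rho_rest = 0, threshold = 1, tau = 20 steps, sigma = 0.1, refractory = 2
steps, Poisson stimulus rate 0.05/step at amplitude 1.2 (suprathreshold, so
group A fires at the stimulus rate), synaptic increment 0.4 per parent spike
(so a B neuron needs ~3 near-coincident parent spikes to fire), correlation
window 40 frames. Correlations are computed on the membrane-potential
traces over non-overlapping windows; every neuron pair gets an edge
(complete weighted graph), leaving all thresholding to the channel ladder.
Undefined correlations (constant series, which cannot occur at sigma > 0)
are recorded as weight 0.

What the simulator does *not* emulate: calcium-indicator dynamics
(rise/decay kernels, photon noise), recurrent or inhibitory connectivity,
non-stationary behavior states, and the neuron-detection pipeline that
produces real recordings. Passing the simulated discrimination task shows
that the embedding recovers wiring-density differences expressed through
pairwise rank correlations; it does not certify performance on real
calcium-imaging data.

## Evaluation harness

Four classifiers with fixed hyperparameters across all experiments:
single-hidden-layer MLP (128 ReLU units), two-layer MLP (128, 64), both
softmax-output, Adam, 100 epochs, batch size 32 (batch size and the absence
of early stopping are this package's fixed choices); RBF-kernel SVM with
C = 100, γ = 0.1; LDA with tol = 1e-4. Scores come from 10-fold
cross-validation with *stratified* folds — stratification is a deliberate
strengthening of plain random partitioning that rules out degenerate
single-class folds on imbalanced data. Plain accuracy is reported for
balanced benchmarks; balanced accuracy (mean per-class recall) is available
for imbalanced ones. Method pairs are compared with a two-tailed paired
t-test over matched fold scores at α = 0.05; zero-variance score differences
are reported as undefined rather than significant.

## Problem sizes and runtime choices

The shipped validation suite runs the five vertices benchmark at its full
3,000-graph size, and the simulated discrimination task at 100 graphs per
condition with nc = 10 channels — sizes at which the whole suite completes
in a few minutes on one CPU while still exercising every claim at, or near,
the scale the claims are stated for. The acceptance script
(`scripts/acceptance.py`) uses the same sizes.

## Known limitations

- The paragraph-vector clusters tighten with corpus size; below ~150
  replicates per class the five-vertices separation is no longer reliably
  perfect under a linear classifier.
- The ladder ignores negative correlations (see above).
- Exact reproducibility holds for a fixed seed and single-threaded
  execution; embeddings are not comparable across different seeds (the
  paragraph-vector space has no canonical orientation).
- MD5 is used as a fast fixed-width compressor, not for security; digest
  collisions are theoretically possible but irrelevant at corpus scale.
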