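# Methods

`biokg` turns heterogeneous biomedical knowledge into per-entity vector
spaces. This note documents the models and procedures it implements, the
parameters that matter, what the synthetic generators do and do not emulate,
and the design decisions taken where several readings were defensible.

## The knowledge-graph model

The graph schema (*metagraph*) declares entity types (*metanodes*, 3-letter
abbreviations such as GEN for genes/proteins, CLL for cell lines, CPD for
compounds) and typed relations (*metaedges*, e.g. `GEN-ppi-GEN`,
`CPD-trt-DIS`). Conventions:

* Heterogeneous metaedges are stored in one canonical direction
  (`CLL-has-TIS`, never `TIS-has-CLL`); metapaths may traverse either way.
* A metaedge is **directed** only when it is homogeneous with a single valid
  orientation (kinase→substrate phosphorylation, TF→target regulation). In
  metapath expressions the `'_'` mark names the side acting as the relation's
  source: `GEN-_pho-GEN-ass-PWY` walks kinases → substrate pathways,
  `GEN-pho_-GEN-ass-PWY` substrates → kinase pathways. An unmarked directed
  step defaults to source-on-left.
* Data enter as **datasets**: named binary edge lists bound to exactly one
  metaedge. Datasets are kept separate rather than merged, so a metapath can
  be embedded per source or over several sources. Original edge weights or
  confidence scores are not stored: they largely encode annotation or
  detection biases, and no single treatment generalizes across sources; any
  cutoffs are applied upstream during standardization.
* Node identifiers are opaque strings. Vocabulary choices (UniProt, InChIKey,
  ontology ids, …) are the caller's concern; the package never parses
  biological nomenclature.

Annotations against ontological vocabularies are propagated to all ancestor
terms before any cross-referencing (`propagate_ontology`; idempotent and
monotone). Overly general terms are flagged by information content,
`IC(t) = −log2(|entities(t)| / |corpus|)` with the corpus being the union of
all propagated annotation sets (so a sole root scores 0 even in
multi-rooted ontologies), and the lowest-IC quantile (default 5%,
configurable — sources publish their pruned lists rather than a universal
threshold) is removed so that terms like "disease" or "membrane" do not
become super-hubs.

## Standardization of continuous data

**Expression/proteomics** (`binarize_expression`): mean-collapse duplicate
genes and samples → `log2` (skipped when the matrix is already
log-transformed; non-positive matrices are shifted by `1 − min`, flagged in
the output metadata) → quantile normalization across samples (every column
shares one distribution; ties get averaged ranks) → per-gene robust scaling
(subtract median, divide by interquartile range; constant genes scale by 1
with a warning) → per sample, the 250 most positive genes become `upr` edges
and the 250 most negative become `dwr` edges. Boundary ties are broken by
gene id so output is deterministic. A corollary worth knowing: a signature
present in ≥ 25% of samples inflates its own genes' IQR and dilutes their
scores — group structure must be a minority pattern per group.

**Drug sensitivity** (`waterfall_binarize`): cell lines are ranked by
ascending AUC (area under the growth-inhibition curve; low = sensitive).
Lines meeting the sensitivity requirement AUC < 0.9 are *eligible*; on the
eligible ranked curve the elbow is the point of maximal height above the
chord joining its endpoints (exhaustive O(n) scan, deterministic), and cells
strictly before the elbow are called sensitive, with the count clipped to
[1%, 20%] of the full panel. Applying the AUC ceiling before the elbow scan
is a deliberate design choice: on bimodal profiles the sparse lower tail of
the resistant mode otherwise pulls the max-distance point several cells past
the true boundary (order-statistic spacing there exceeds the chord slope),
systematically contaminating the sensitive set. A panel with no line below
0.9 yields an empty set; a panel with resistant lines below 0.9 can still
yield a few spurious calls bounded by the clips — the method sees only the
curve's shape.

**Perturbation experiments** (`reify_perturbagens`): each perturbation
becomes its own perturbagen (PGN) node; the perturbation kind maps to the
PGN→gene relation (loss-of-function kinds → `pdw`, gain-of-function →
`pup`), and the experimental outcome becomes a second PGN edge. "A shRNA
silencing gene A upregulates gene B" is thus `PGN-pdw-A` + `PGN-upr-B`.

**Vocabulary harmonization**: `tfidf_crossref_map` encodes each term as a
binary vector over shared cross-reference ids, TF-IDF-transforms the stacked
matrix (smoothed idf `ln((1+N)/(1+df)) + 1`, L2-normalized rows — stated
because variants change cosines) and maps pairs with cosine ≥ 0.5.
`cluster_pathways` merges pathways of ≥ 20 genes whose overlap coefficient
reaches 0.9 into SuperPaths (transitive closure) and links SuperPaths at
Jaccard ≥ 0.7.

## Metapath collapse: degree-weighted path counts

A metapath of length L is collapsed into one source × target matrix by
chaining degree-normalized adjacencies:

    W_i = D_row^w · A_i · D_col^w ,   w = −0.5 by default
    DWPC = W_1 · W_2 · … · W_L

Degrees are computed **within each dataset**, on the traversal-oriented
adjacency, so a hub in one source is damped there without penalizing its
sparse appearances elsewhere. The product equals, entrywise, the sum over
all source→target walks of the product of traversed node degrees raised to
w; `w = 0` recovers raw path counts (the property-test oracle enumerates
paths explicitly). Between consecutive steps the shared node universe is the
intersection of the previous dataset's targets and the next dataset's
sources; an empty intersection is a hard "disconnected metapath" error.
Directed homogeneous steps traversed against their declared direction use
the transpose.

`'+'`-combined relations (`CLL-dwr+upr-GEN-dwr+upr-CLL`) are **zipped
positionally** across the steps carrying them — the example expands to the
"mimicking" variants (dwr,dwr) and (upr,upr), while `CLL-upr+dwr-GEN-
dwr+upr-CLL` gives the "reversion" variants (upr,dwr)/(dwr,upr). One network
is computed per variant and per dataset combination; length-1 metapaths
merge by binary edge union, longer ones by summing DWPC values (commutative
and associative).

**Edge capping.** Long metapaths connect almost everything to almost
everything with tiny weights; an untamed network needs far more walks for
the skip-gram stage to resolve its weight distribution. Each node therefore
keeps only its top `clamp(round(0.05 · n_possible), 3, 250)` neighbours by
weight (`n_possible` = opposite-side universe size; ties broken by weight
descending then neighbour id). The cap is evaluated from the row and the
column perspective and an edge survives when **either** endpoint keeps it —
the intersection rule could disconnect low-degree nodes. The per-side
selections are retained on the result (`row_kept`/`col_kept`); the union is
what the walker consumes. Capping is idempotent and never alters surviving
weights.

**Component filtering.** Connected components covering < 5% of the entities
are dropped; if the surviving network retains < 50% of the nodes the
metapath is flagged REJECTED and `embed_metapath` aborts — an embedding of a
fragment would silently misrepresent the entity space.

## Embedding: biased random walks + skip-gram

Per-node DWPC weights are rescaled to sum to 1 and used as next-step
probabilities (uniform on unweighted L1 networks). With walk-bias parameters
p = q = 1 (the default) the walker is first-order Markov, implemented with
per-node alias tables and vectorized over all walkers; the general
second-order (p, q) walker exists but is a slower reference implementation.
Every non-isolated node anchors 100 walks of 100 nodes (defaults), with the
anchor order reshuffled each repetition. Bipartite networks are walked on
the block adjacency, alternating sides; homogeneous matrices are
symmetrized.

The corpus is fed to a skip-gram model with negative sampling, written as a
single-threaded numba kernel following the classic word2vec conventions:
dynamic (randomly shrunk) context window of 5, 5 negative samples from a
unigram^0.75 table, 5 epochs, initial learning rate 0.025 with linear decay,
sigmoid lookup table clipped at ±6, no frequent-token subsampling (node
frequencies in walk corpora are near-uniform, so subsampling would be a
no-op at best). Output vectors are 128-dimensional by default.

**Reproducibility contract:** walks and training are pure functions of
(network, config, seed); the kernel is sequential, so embeddings are
bit-identical across runs. There is no multi-threaded mode.

## Evaluation and characterization

`reconstruction_auroc` asks whether an embedding can reassemble the network
it was trained on: per edge, the cosine distance of its endpoints is
compared against 100 random node-pair "permutations" (both endpoints
resampled uniformly within the correct entity side; self-pairs and true
edges are rejected and resampled — the rejection is a documented choice).
The AUROC is the Mann–Whitney rank statistic with ties mid-ranked, so it is
invariant to monotone transforms of the distances. Embeddings with AUROC <
0.8 are marked not retained. For weighted networks the evaluation is
repeated on the per-node top 1% / 25% / 50% closest-neighbour subsets by
DWPC weight; tighter subsets tend to score higher (reported, not asserted —
the trend is stochastic). An undefined AUROC (one class empty, or fewer than
two covered nodes) is reported as missing, never as 0.5.

`recapitulation` runs the same statistic against orthogonal reference
networks, reporting node coverage alongside. Two helpers derive per-side
similarity networks from a bipartite reference: TF-IDF cosine top-5
neighbours per entity, and shared-neighbour-count top-3 (ties by id).

## Distance statistics

Raw cosine distances are incomparable across embedding spaces and across
nodes of different connectivity (general terms sit close to everything).
`corank_pvalue` normalizes both: rank b in a's ascending exact
cosine-distance list (1-based, self excluded, ties by distance then id),
normalize by the n−1 other covered nodes, and keep the geometric mean of the
two directions. A mutual nearest-neighbour pair among 100 covered nodes
scores √(1·1)/99 ≈ 0.01; a mutually farthest pair scores exactly 1. The
normalization by n−1 (rather than n) is what makes the upper bound exact and
keeps P in (0, 1]. These are empirical quantiles, **not** significance
levels. For random pairs in an isotropic random embedding the two co-ranks
nearly coincide (both approximate the quantile of the pair distance under
the common distance distribution), which is why the P values are close to
Uniform(0,1) — a property the test suite checks by Kolmogorov–Smirnov.

Null models come from degree-preserving double-edge swaps (10 successful
swaps per edge by default; bipartite networks swap targets only so sides are
preserved; self-loops and duplicates are rejected). Sweeping P-value cutoffs
(50 log-spaced points in [0.001, 1]) over real versus permuted query edges
gives fold-change curves, FC(c) = real count / mean null count (null mean
floored at one edge, raw counts reported alongside), and the empirical FDR
cutoff: the largest grid cutoff at which the mean fraction of covered null
edges stays ≤ the nominal rate (step function, no interpolation). The
phrase "minimum P value needed to cover no more than 5%" admits a stricter
reading — the grid point below — exposed via `conservative=True`.
`support_categories` then labels query edges by which embedding spaces pass
the cutoff: covered by the direct-interaction metapath and another ("known
and supported"), only by it ("known"), only by others ("supported"), or by
none ("potentially novel").

## Synthetic study conditions

The generators in `biokg.fixtures` produce the structures each stage
assumes, sized so the full pipeline runs in minutes on one CPU (defaults ≤
2,000 nodes, ≤ 50,000 edges):

* `planted_partition_network` — stochastic block model with round-robin
  block assignment; returns ground-truth labels.
* `synthetic_kg` — GEN/CPD/DIS/PWY metagraph whose layers share one block
  assignment, so multi-step metapaths carry recoverable signal.
* `synthetic_expression` — log-normal baseline (per-gene mean ~N(7,1) on
  log2 scale, noise sd 0.5) with group-specific markers shifted by a fixed
  log2 effect.
* `synthetic_drug_response` — bimodal AUC: sensitive ~N(0.3, 0.05) with
  probability 5%, resistant ~N(0.92, 0.03), clipped to [0, 1].

All generators are pure functions of their seeds. What they do **not**
emulate: scale-free degree distributions, correlated noise and batch
effects, annotation-depth biases, overlapping communities, and the sheer
size of real resources. Passing tests therefore demonstrate that the
machinery is correct and calibrated on graphs with planted, recoverable
structure — not that any particular biological claim transfers.

The acceptance script (`scripts/acceptance.py`) measures two quantities at
fixed problem sizes chosen to finish in a few minutes on one CPU: the
reconstruction AUROC of a 500-node, 10-block planted-partition embedding
(p_in=0.3, p_out=0.01; 100 walks × length 100; 100 negatives per edge), and
the maximum waterfall sensitive fraction over 50 profiles of 500 lines.

## Numerical choices and degenerate inputs

* Top-k selections everywhere break ties deterministically (weight/score
  first, then id).
* Round-half-up for the edge-cap budget before clamping.
* Sparse matrix products never materialize explicit zeros.
* Isolated nodes are skipped by the walker with a warning; a network with no
  edges at all is an error.
* A vocabulary of fewer than 2 nodes cannot be embedded (error).
* Self-loops are dropped on dataset construction; none of the supported
  relation types requires them.
* Seeds derived from a master seed stay below 2^31.

## Known limitations

* The second-order (p ≠ 1 or q ≠ 1) walker is a per-walker Python loop —
  correct but slow; the production path is p = q = 1.
* Bipartite walk graphs require the two side universes to use disjoint id
  sets (entity-typed prefixes in practice); a collision raises.
* `cap_edges`'s union rule means a node's *incident* edge count can exceed
  its own budget when the opposite side elects it; the per-side budgets are
  exact, the union is a floor on connectivity.
* Metapaths mixing several multi-relation (`'+'`) steps must use the same
  arity on each (zip semantics); cross-products are deliberately not
  generated.
* No attribute-aware or GNN-style embedding; nodes outside the retained
  network simply have no vector.
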