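# Methods

This note records the modelling choices behind `diseasetax`: what the
algorithms assume, where the published descriptions of these techniques
leave freedom, how that freedom was resolved, and what the synthetic
world does and does not establish.

## Similarity model

Diseases are compared solely through the Jaccard index of their
associated gene sets; no prior knowledge of disease relationships enters
the similarity matrix. Gene identifiers are opaque, case-sensitive
strings — HGNC-symbol normalisation across database versions is
deliberately out of scope, and associations are always deduplicated
(multiplicity across source databases carries no weight). A disease with
an empty gene set has no defined similarity to anything; such diseases
are rejected at similarity time rather than silently scored 0, because
scoring them would mask a pipeline error — pruning them from the
reference is a separate, explicit step.

## Reference preprocessing

**Pruning with reconnection.** Removing geneless terms can disconnect a
reference DAG. Each retained node is therefore re-attached to its
*nearest retained proper ancestors*: edge (p, x) exists in the pruned
hierarchy iff some original path p→…→x passes through no other retained
node. The one-level rule ("connect a deleted node's parents to its
closest annotated descendants") does not by itself cover chains of
consecutively deleted nodes; the nearest-retained-ancestor closure is the
unique extension that (a) preserves ancestor/descendant reachability
restricted to retained nodes and (b) is idempotent. Both properties are
verified against a Floyd–Warshall closure oracle in the test suite.

**MeSH duplicate names.** MeSH tree-number tables may place one disease
name at several positions; all positions are merged into a single node,
turning the tree into a DAG. A merge that would create a self-loop drops
the edge with a warning. A merge creating a longer directed cycle (name A
above B in one subtree and B above A in another) raises a structural
error instead: hierarchies in this package are invariantly acyclic, and
silently breaking such a cycle would require an arbitrary edge choice.
Real MeSH category C data is tree-like enough that this case has not been
observed; the error is the honest response if it ever occurs.

**Subnetwork roots** are matched by exact, case-sensitive name. Fuzzy
"approximately corresponding" matching between vocabularies cannot be
specified reproducibly, so root names are a user-supplied input.

## Parent Promotion

The dendrogram comes from complete-linkage agglomerative clustering of
the Jaccard distances. Conversion to a named tree processes merges
bottom-up with one *representative* per cluster; at each merge only the
two current representatives compete (not every member of the merged
cluster), the representative with more citations becomes the parent of
the other, and the loser is permanently demoted. This
representative-vs-representative reading is the only one under which a
previously promoted disease keeps its own children when its cluster is
absorbed by a better-cited term.

Two tie-breaking rules replace what reference implementations delegate to
library defaults, and make the whole pipeline deterministic and
input-order invariant:

- **Clustering merge ties** (equal inter-cluster distance, common when
  many disease pairs share no genes): merge the pair whose
  (smallest-member-id, smallest-member-id) sorted key is
  lexicographically least.
- **Citation ties**: the larger count wins; at equal counts the
  lexicographically smaller disease id is promoted.

Citation counts are supplied as a TSV (`disease_id<TAB>count`). A live
PubMed E-utilities fetch is not included: the exact query form (MeSH-
qualified vs free text) behind published counts is unknowable, a network
dependency would make tests non-hermetic, and no HTTP client is assumed.

## MWST baseline

Descriptions of this baseline mix "minimum weight" with "connects
diseases by their highest similarity"; both are satisfied by weighting
edges with distance = 1 − similarity, so the minimum-weight tree is the
maximum-similarity tree. Kruskal's algorithm consumes edges in sorted
(weight, min(id), max(id)) order — with sparse gene data many weights tie
at 1.0, and an undocumented tie order would make results irreproducible.
The unrooted tree is rooted at the most-cited disease and oriented
outward by BFS.

## Evaluation metrics

- **EC** counts directed reference edges reproduced in the inferred
  hierarchy, normalised by the reference edge count. No inferred-node
  filter is applied: an edge to a node absent from the inferred
  hierarchy simply cannot match.
- **AC** averages per-term ancestor Jaccard over terms present in both
  hierarchies; terms with no ancestors in either (roots in both) are
  excluded rather than scored — 0/0 is undefined, not zero.
- **AP/AR** average per-term HP and HR over shared terms, skipping terms
  whose denominator (inferred resp. reference ancestor set) is empty.
- **F** is the harmonic mean of the *averaged* AP and AR (macro-F). The
  per-term formula leaves the aggregation ambiguous; macro-F matches how
  (precision, recall) pairs are conventionally reported alongside a
  single F. Per-term HP/HR/F values are exposed via
  `evaluation.per_term_scores` for users who prefer the other
  aggregation.
- For tree-shaped inference output the universes "terms in the inferred
  network" and "terms in the reference" coincide after pruning; for
  general inputs the intersection of node sets is used throughout.

Multi-root references (forests) are supported; the "root in both"
exclusion applies per term.

## Synthetic world

`SyntheticConfig` defaults state the world: 50 terms (MeSH-subtree
scale), fan-out ≤ 3, 5 novel genes per term, 80% of the parent's gene set
inherited by each child, no noise, citations decaying geometrically from
10⁶ at the root (decay 0.5) with jitter bounded so counts never reorder
across adjacent depths. The generative model — child inherits a fraction
of the parent's genes plus novel ones — is the simplest one making both
the clustering signal (gene overlap decays with tree distance) and the
rooting signal (citations decay with depth) recoverable. One random
stream per seed is consumed in the order taxonomy → associations →
citations, so all outputs are bit-reproducible.

`make_separable_fixture` guarantees exact recovery rather than merely
encouraging it. It builds the dendrogram that *should* reconstruct the
tree (each node folds in one child subtree at a time), attaches one
shared gene to every dendrogram cluster, and pads every term's gene set
with private genes to a common size s. The gene overlap of two terms then
equals the number of dendrogram clusters containing both, so the Jaccard
distance 1 − o/(2s − o) is an exact ultrametric aligned with that
dendrogram: heights strictly increase along every nesting chain, ties
occur only between disjoint clusters (where merge order is immaterial),
and complete linkage reproduces the dendrogram exactly. Citations
strictly decrease with depth, so every merge promotes the true parent and
EC = AC = AP = AR = F = 1. An optional `noise` argument rewires a
fraction of associations afterwards, which breaks the guarantee and is
used to demonstrate graceful degradation.

What a green synthetic test does **not** establish: performance on real
MeSH/DO snapshots, where gene annotations are sparse, biased by research
history, and shared across distant branches; where many disease pairs
have similarity exactly 0 (massive tie-breaking); and where citation
counts only loosely track term generality — a well-studied specific
disease can outrank its own parent and be promoted above it. Source-
specific biases (Mendelian vs GWAS curation) are not modelled beyond the
uniform noise parameter.

## Numerical and degenerate-input choices

- All metrics are exact rational arithmetic over small integers in
  float64; no tolerance is needed below ~1e-12.
- Clustering and both inference methods require ≥ 2 diseases; the
  similarity of a geneless disease, a missing citation entry, an
  edgeless reference (EC), and hierarchies sharing no eligible term all
  raise typed errors rather than returning sentinel values.
- `generate_citations` raises a config error when `citation_base` is too
  small to keep counts strictly decreasing between adjacent depths.
- Recursion in the separable-fixture construction follows the tree
  depth; random taxonomies at the supported scales stay far below the
  interpreter recursion limit.

## Known limitations

- No MeSH↔DO vocabulary mapping: associations must already use the
  reference's term space.
- OBO parsing reads `is_a` only; `part_of` and other relationship types
  are ignored.
- Confidence-weighted association sources must be binarised upstream.
- The clique-based ontology-learning comparator and the alignment of
  unlabeled gene-set nodes to term space are out of scope, so evaluation
  assumes node identity between hierarchies.
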