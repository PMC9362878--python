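# Methods

## The cluster-flow graph

Input is a cell-by-resolution matrix of integer cluster labels over a
strictly increasing grid r₁ < r₂ < … < r_T (at least two values), plus
the matching cell-by-gene non-negative expression matrix. Expression is
assumed already normalized; the package applies no normalization of its
own and accepts log- or linear-scale values as given (overlays use the
values as provided — a deliberate choice, since the appropriate scale
depends on upstream preprocessing).

Labels are first permuted per column so that label 0 is the largest
cluster (ties keep the original label order, making the operation
idempotent); a `{original → new}` map is retained per column. Each
(resolution, label) pair becomes a node identified as
`"<resolution>_<label>"`, with the resolution string preserved exactly as
it appeared in the input header so identifiers never drift with float
formatting. Flows between adjacent columns j and j+1 are the nonzero
cells of the source-label × target-label contingency table; each flow
stores its member cell set, its count m, and the two proportions
m/size(source) and m/size(target). Because each column is a partition of
the same cells and edges connect only adjacent columns, the graph is
acyclic and conservation is exact in integers: every interior node's
size equals the sum of its incoming and of its outgoing flow counts.
`SankeyGraph.validate()` asserts all of this and is run at build time.

Flows deliberately connect only consecutive grid columns, and no
proportion threshold is applied when building — the data structure is
lossless, and filtering is a render-time option in the HTML viewer.

### Layout

x is the column index scaled to [0, 1]; node heights are proportional to
size, with 5% of each column's height distributed as gaps. Vertical
order within a column comes from the classic layered barycenter
heuristic: 4 rounds of alternating left-to-right and right-to-left
sweeps, each placing a node at the flow-count-weighted mean position of
its neighbors in the fixed adjacent column, ties broken by node label.
The crossing count is evaluated after every round and the best ordering
seen is kept, so the final layout is deterministic and never worse than
the initial size-order layout. Optimal crossing minimization is NP-hard
and out of scope.

## Overlays

**Single-gene painting.** Each flow's raw value is the arithmetic mean
of the gene over its member cells. Values are min–max normalized —
globally over all flows by default (one scale bar), or per column pair —
and looked up in a named Matplotlib colormap. A degenerate constant
range maps every flow to the colormap midpoint.

**Co-expression (GEP).** For an ordered geneset of exactly three genes
and a flow of m cells, GEPᵢ is gene i's summed expression over the
flow's cells divided by the geneset's total summed expression over those
cells. Defined triples sum to 1 to within accumulation error (≤ 1e−9
asserted); they are invariant to cell order and to scaling all three
genes by a common positive constant. A flow in which the geneset is
entirely silent has an undefined GEP; it is painted a configurable
neutral gray (#BEBEBE) rather than given an arbitrary coordinate. The
gene → channel map follows geneset order (first → red, second → green,
third → blue); channels are round-half-away-from-zero of 255·GEPᵢ,
emitted as uppercase hex. The mapping is linear by design — a colormap
lookup would break the identity between ternary position and color.

**Ternary chart.** One point per flow with a defined GEP, at the triple's
barycentric coordinates, colored by the same hex, sized 2·log₂(m).
Single-cell flows have true size 0; the renderer draws them at a 1-px
floor while the stored value remains 0.

## Cluster metrics

Silhouette uses Euclidean distance in the user-supplied embedding (the
same metric as the kNN graph): s(i) = (b−a)/max(a,b) per cell, 0 for
singleton clusters and for the degenerate a=b=0 case, averaged per
cluster. scikit-learn provides the per-sample computation; tests verify
it against an independent O(n²) implementation of the formulas.
Normalization for painting is the affine map (s+1)/2 — a bijection of
the silhouette's full range onto [0, 1], chosen over min–max so that the
color scale is comparable across datasets; min–max (constant input →
0.5) is available for arbitrary ingested metrics. Calinski–Harabasz and
Davies–Bouldin are partition-level quantities and are attached to every
node of their column.

Marker tags are two-sided Wilcoxon rank-sum tests (normal approximation
with tie correction) of each cluster against the rest of its column,
ranked by p-value with ties broken by descending mean difference, then
gene id; Benjamini–Hochberg FDR is reported alongside raw p. The top 5
genes populate the node hover. These tags are descriptive labels, not a
calibrated differential-expression analysis — no pseudobulking, no
model-based testing.

Enrichment and activity scores are computed by external services and
tools; the package ingests them as generic per-cluster annotation tables
keyed by (resolution, label), strict or skip-with-log permissive.

## Stable-community tracing

A flow is stable when min(m/size(source), m/size(target)) ≥ τ. The
definition is symmetric, and for τ > 0.5 pigeonhole gives at most one
stable flow into and out of any node, so stable flows chain into unique,
node-disjoint maximal paths. The default τ = 0.9 demands that both
endpoints share 90% of their cells. A path's score is its weakest
mutual proportion; its core is the intersection of all step member sets.
For τ ≤ 0.5, branching is resolved deterministically toward the higher
mutual proportion (then larger count, then target id), with each flow
used at most once. The mutual-proportion rule is this package's explicit
construction for "tracing stable communities"; other definitions (e.g.
one-sided proportions) would not be symmetric or would not guarantee
disjoint chains.

On a hierarchy where one population persists across the whole grid and
another splits 50/50 at a known resolution r, tracing at τ = 0.9 yields
a full-span path for the persistent population and ends the splitter's
path at the column immediately before r (the flows into the split carry
only half of the parent), with both halves starting fresh paths at r.
This is the exact sense in which a path end localizes a split.

## Resolution scan

kNN is exact brute-force Euclidean search in the embedding, ties broken
by cell index. The SNN weight between u and v is the Jaccard overlap of
their neighborhoods (each cell's own index included, so mutually nearest
twins reach weight 1); edges below the prune threshold are dropped.
Defaults k = 20 and prune = 1/15 follow widespread single-cell practice;
they are conventions, not reproductions of any published configuration,
and both are configurable. Community detection per grid value is
delegated to leidenalg (RB-configuration modularity on the weighted SNN
graph, 2 iterations, fixed seed shared across columns); the package does
not reimplement modularity optimization, and the core graph accepts any
clustering's label matrix. Disconnected SNN graphs are fine — components
are partitioned independently. Mean cluster count is expected to be
non-decreasing in resolution on hierarchical data and is asserted
non-strictly in tests; Leiden gives no hard guarantee of monotonicity.

## Synthetic data

The generator plants a tree of cluster prototypes. Leaves carry cell
counts and marker gene indices; internal nodes carry the resolution at
which they split. Cutting the tree at each grid value produces the
ground-truth assignment columns, which are successive refinements by
construction — so expected flows are exactly the tree's refinement
edges (every backward proportion is 1), and split columns are known.
Expression is prototype × lognormal(σ = 0.4) multiplicative noise on a
baseline of 0.5 with markers elevated to 5–6 — emulating normalized
post-QC expression. The embedding is the first 10 principal components
of the generated matrix (deterministic full SVD).

The default preset emulates the shape of a PBMC sweep: 2700 cells, 8
leaves in a three-level hierarchy, grid 0.1–0.5 in steps of 0.1, with
genes 0–2 designated co-expression markers of the three major branches
so GEP triples reach all three ternary corners. What the fixtures do
*not* model: count-level noise, dropout, library-size variation, batch
effects, doublets, or continuous trajectories. Tests passing on these
fixtures demonstrate the graph accounting, statistics and tracing are
correct; they do not certify clustering quality on real data.

Problem sizes in the test and acceptance runs (2700-cell preset, 50
random matrices up to 10⁴ cells, 150-cell silhouette fixtures) were
chosen so the full pipeline and its quadratic oracles stay comfortable
on a single CPU.

## Serialization

The JSON spec (schema version 1.0, structural schema shipped as
`viz-spec.schema.json`) stores nodes with layout and hover content,
links with counts, proportions and per-overlay paints, the ternary point
set, and an overlay registry. Construction order and formatting are
fixed, so export → import → export is byte-identical; a hand-written
structural validator enforces the schema (including referential
integrity: link endpoints must exist, paints must be registered) before
any write or render. The HTML viewer embeds the spec verbatim and draws
it as SVG with a small amount of vanilla JavaScript — overlay switching
and the proportion-filter slider operate entirely on the precomputed
document, so the file is portable and needs no server.

## Known limitations

- Flows across more than one grid step are not represented; a cluster
  that vanishes and reappears is two paths.
- The ternary view is defined for exactly three genes; the GEP ratio
  generalizes, the chart does not.
- Stable paths with τ ≤ 0.5 depend on the documented deterministic
  tie-break; only τ > 0.5 gives a canonical decomposition.
- The barycenter layout is a heuristic; pathological graphs can retain
  avoidable crossings (never more than the size-order baseline).
- Per-cluster annotation ingest assumes externally computed scores; no
  enrichment statistics are performed in-package.
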