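# Methods

This note documents the statistical model, the algorithmic choices that
were genuinely open, the synthetic-data generator, and the numerical
details of `setnet`.

## Enrichment model

Overlap significance is the one-sided over-representation Fisher exact
test. With universe size N, user-list size a and library-set size b (both
after restriction to the universe) and overlap k, the p-value is the
hypergeometric upper tail P(X ≥ k) for X ~ Hypergeom(N, b, a). One-sided
was chosen because the question asked of an enrichment screen is always
"is this overlap larger than chance", never "smaller"; the under-
representation tail is not informative for list integration. The null
treats genes as independent draws — a simplification shared by all
contingency-table enrichment tests; correlated gene sets (co-regulated
modules) make the test anti-conservative, and users should read borderline
p-values accordingly.

Tail sums are evaluated through `scipy.stats.hypergeom.sf`, which works in
log space; universes of tens of thousands of genes cause no overflow. The
test suite checks agreement with an exact integer-rational enumeration to
relative error 1e−9 over thousands of (N ≤ 60, a, b, k) instances.

### The background universe N

N is not observable from a user list and materially changes p-values, so
it is an explicit policy:

* `library` (default): N = |union of the library's member genes|. The
  library defines the annotation space, so it also defines the population;
  this is reproducible and self-contained. User genes outside the universe
  are dropped from a (and counted on the result), not added to N.
* `union`: library universe ∪ all user-list genes — appropriate when user
  lists contain genes the library never annotates and dropping them would
  misstate a.
* `custom`: an explicit gene list (e.g. all genes on the array).

### Multiple-testing correction

Per user-list column, over the selected library's sets: Bonferroni
(min(1, n·p)) and Benjamini–Hochberg step-up (sort ascending,
q_i = p_i·n/i, cumulative minimum from the largest rank, cap at 1,
returned in input order; delegated to
`statsmodels.stats.multitest.multipletests`). Correcting per column
matches the workflow of sorting and reading one input list's results; a
`matrix` scope (one family over all cells) is available for analyses that
report the whole matrix at once. Ranked tables order by raw p ascending
with ties broken by descending overlap k, then label — raw p is the
primary ranking because both corrections are monotone in it within a
column.

## Expansion model

Seeds are the input genes present in the background network. For every
unordered seed pair at background shortest-path distance d with
2 ≤ d ≤ `max_steps`, *all* shortest paths are enumerated (a single
arbitrary path would make output depend on adjacency iteration order; the
all-paths rule is deterministic and order-independent). Direct seed–seed
edges (d = 1) are always kept; pairs farther apart than `max_steps` are
left unconnected rather than erroring, since sparse background coverage is
normal.

Specificity of a candidate intermediate v is
|neighbors(v) ∩ seeds| / degree(v), computed against the **original**
background network. Hubs that touch everything therefore score low even
when they connect many seeds — the point of the filter is to prefer nodes
that interact preferentially with the input list. Filtering is single
pass: candidates below the cutoff are removed together with every path
that traverses them, and paths are not re-grown afterwards. A consequence
is that a high-specificity node whose only admitting paths also cross a
filtered node is dropped too; this keeps the invariant that every reported
intermediate lies on at least one fully admitted path. The cutoff is
inclusive (specificity ≥ cutoff admits).

The subnetwork's edges are the union of admitted-path edges plus
background edges among seeds — *not* the induced subgraph: an edge between
two admitted intermediates that lies on no admitted path carries no
evidence under the path model and is excluded.

Intermediates are ranked by subnetwork-link count / background degree
(descending), ties by descending subnetwork links, then label. Seeds
missing from the background network are excluded from path finding but
retained (in input order) when the subnetwork is converted back to a list:
expansion should never silently shrink the user's list.

## Co-annotation networks

The co-appearance level of two genes across a library is the Jaccard index
of their set-membership profiles: |sets containing both| / |sets
containing either|, 0 when neither is annotated. It is symmetric, lies in
[0, 1], equals 1 exactly for identical membership and 0 for disjoint
membership; the corresponding distance is 1 − similarity. The measure
lives behind a single function so an alternative (co-occurrence count,
cosine) can be swapped without touching the graph builder. The edge cutoff
is inclusive and required; at cutoff 0 every universe pair qualifies by
definition (score 0 ≥ 0), which is degenerate but kept for monotonicity —
practical networks use a positive cutoff.

## Network of lists

Edges require Bonferroni-corrected p strictly below alpha (default 0.05).
User–user overlaps are tested against the same universe and corrected over
the number of user pairs — a separate, smaller family than the
user-vs-library columns, because the two edge types answer different
questions; the behaviour sits behind a flag (default on). Library sets
with no significant edge are omitted from the graph entirely; remaining
set nodes are classed `single_overlap` / `multi_overlap` by the number of
input lists they hit, and input nodes always keep class `input` even when
connected to each other. Colors are a rendering concern and are not
stored; the class attribute travels through GraphML/SIF export instead.

## File formats

* **GMT**: tab-delimited; per row: name, description, then symbols.
  Symbols are upper-cased (the convention for human Entrez symbols),
  deduplicated silently with a per-list counter (real GMT files contain
  duplicates), empty cells dropped. Descriptions are preserved verbatim
  and never used in computation. Unix and Windows endings are read;
  writing uses Unix endings. Round-trip identity is property-tested.
* **SIF**: `nodeA<TAB>relation<TAB>nodeB`; extra trailing node fields are
  accepted as additional edges and a single-field row denotes an isolated
  node (both Cytoscape conventions — the latter is what makes
  write∘read an identity for subnetworks containing unconnected seeds).
  Relation strings are preserved as edge attributes but ignored by
  algorithms; networks are undirected, self-loops are dropped and
  duplicate or reversed edges merged, with counters reported.
* **Weighted pair tables**: 3-column TSV, optional header auto-detected by
  a non-numeric third field in row 1; duplicate pairs keep the maximum
  weight before thresholding (the conservative merge for correlation-like
  scores).
* **Plain lists**: one symbol per line, `#` comments ignored.
* **Synonyms**: optional two-column alias → canonical table applied at
  normalization time; aliases must map directly to canonicals (no chains).
  No synonym database is bundled — the hook accepts whatever mapping the
  user trusts.

## Synthetic data

`setnet.synthetic` generates everything the tests and the acceptance
script consume; all generators are pure functions of a `FixtureSpec`
(integer seed → decoupled `numpy` Generator streams; identical specs give
byte-identical files).

Defaults emulate a desk-scale enrichment screen: a 2,000-symbol universe,
50 sets of 50–150 genes drawn uniformly without replacement, and a planted
user list of 50 genes sharing exactly 40 (fraction 0.8) with the library's
first set — the remainder drawn from outside that set, so the planted
overlap count is exact by construction. Background graphs: preferential
attachment (Barabási–Albert, n=100, m=2 by default) as a rough proxy for
the heavy-tailed degree distributions of interaction networks, plus
Erdős–Rényi and exact chain/star topologies for oracle tests.

What the generator does **not** emulate: correlated set membership
(pathway hierarchies, GO term nesting), gene-level synonym noise,
experimental false positives, or the degree correlations of real
interactomes beyond preferential attachment. Passing tests therefore
demonstrate algorithmic correctness under the stated null, not performance
on any particular real library or interactome.

## Problem sizes and numerics

The test suite's heavy checks use: ~3,000 Fisher instances against exact
rational arithmetic; 1,000 random p-vectors (lengths 1–200) against an
independently coded step-up; 200 planted-enrichment replicates; 500 random
connected graphs (≤ 12 nodes) against exhaustive path enumeration; 100
GMT and 100 SIF round trips. The whole suite runs in well under a minute
on one CPU.

Numerical details: p-values are clamped to (0, 1]; correction inputs are
validated to (0, 1] and rejected otherwise; fisher comparisons in tests
use relative tolerance 1e−9 (the accuracy scipy's log-space tail delivers
comfortably at these sizes); all sorting tie-breaks are total orders
(label as the last key), so every output is deterministic.

## Known limitations

* Symbols only — no cross-namespace ID mapping or orthology.
* No rank-based enrichment (GSEA-style KS/Wilcoxon statistics).
* The independence null ignores gene–gene correlation.
* Strict shortest-path semantics: no Steiner-tree optimization or
  probabilistic path weighting.
* Layout/visualization is delegated to Cytoscape via SIF/GraphML export.
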