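# Methods

## Similarity model

The package scores GO term pairs by propagating a semantic contribution
through the ancestor DAG. For a query term A, the ancestor closure T_A is
built by upward traversal over a configured relation set — `{is_a, part_of}`
by default, `{is_a, part_of, regulates}` for the regulates-aware variant
(the positive/negative regulation sub-relations are collapsed onto a single
`regulates` type because they share one contribution constant). Traversal
stays inside A's namespace unless `cross_namespace=True`; the ontology does
contain cross-namespace `part_of` edges, but all similarity analyses here
are per-namespace, so stopping at the boundary is the default.

Each edge into an ancestor t carries weight `w_e = 1/(c + nc(t)) + d`,
where:

* `nc(t)` — the number of **distinct direct children of t in the full
  ontology** under the configured relations, not children inside T_A. The
  point of the measure is that a crowded ancestor (a generic term) passes
  little contribution to any one child; counting inside the closure would
  erase exactly that effect.
* `d` — per-relation contribution floor: 0.4 (`is_a`), 0.3 (`part_of`),
  0.2 (`regulates`).
* `c` — a positive constant, default 0.67. With `d ≤ 0.4` and `nc ≥ 1`,
  `c ≥ 2/3` is the smallest value keeping every weight in (0, 1], so the
  configuration validator rejects smaller values unless an explicit
  `allow_unsafe_c` flag is set; even then the weight computation raises if a
  concrete weight leaves (0, 1].

S-values are computed by dynamic programming in topological order:
`S_A(A) = 1`, and for every proper ancestor the maximum of
`w_e × S_A(child)` over its children **within the closure** — children
outside T_A are not ancestors of A and have no S-value, so the within-closure
reading is the only well-defined one. This equals the maximum weight-product
over descending paths, which is how the test oracle recomputes it by
exhaustive enumeration. Ties between paths cannot change the maximum, so no
tie-break policy is needed. Pair similarity follows as the pooled S-mass of
shared ancestors normalised by the two semantic values; it is symmetric, 1
exactly for identical terms, and 0 only for ancestor-disjoint pairs (possible
only in fragmented namespaces).

Setting `method="wang"` replaces the children-count weight with per-relation
constants (0.8 `is_a`, 0.6 `part_of` — the conventional values for the
constant-weight measure; configurable since different tools restate them
differently). This baseline shares all other machinery.

Ancestor graphs are memoized per term inside `TermSimilarityProvider`; the
cache only reuses deterministic per-term results and cannot change values.
Similarities are computed and compared at full double precision; the CLI
additionally prints a 3-decimal display column, matching how such values are
usually tabulated.

## IC baselines

IC(f) = −ln P(f), with P(f) the propagated annotation count of f (raw count
of f plus every descendant, each term counted once) divided by the
propagated count at f's namespace root. Natural log: no base is canonical,
any base rescales Resnik uniformly and cancels in Lin. Per-namespace totals
are used because every analysis here is per-ontology. Terms with zero
propagated count get NaN ("undefined") rather than infinite IC and are
excluded from downstream statistics. Lin similarity with both ICs zero is
defined as 0 (no information, no evidence of similarity) with a warning.
The children-count analysis groups terms by `nc`, drops groups with
`nc > 100` (extreme, near-zero-IC points) and groups whose mean IC is not
positive (log undefined), and reports Spearman and Pearson correlations of
log mean IC against `nc`; fewer than three surviving groups is an error
because a correlation over two points is meaningless.

## Gene similarity

With M the m×n matrix of term similarities between two genes' annotation
sets, row maxima M_i and column maxima N_j ("best matches"):

* `Avg` = mean(M); `Max` = max(M)
* `ABM` = (ΣM_i + ΣN_j)/(m+n) — the pooled best-match average, the default
* `BMA` = ½(mean M_i + mean N_j); `BMM` = max(mean M_i, mean N_j)

`BMA`/`BMM` follow the conventional directional-average definitions, chosen
for consistency with `ABM` being their (m+n)-pooled variant. All five are
symmetric and reduce to the single term similarity for single-term genes;
`Max ≥ BMM ≥ ABM` and `Max ≥ Avg` hold identically. Genes with no terms in
the requested namespace are excluded from pairwise matrices and reported,
since real pathway genes frequently lack annotations in one of the three
ontologies.

## Clustering

Affinity propagation over the gene similarity matrix, delegated to
scikit-learn with a precomputed affinity: 500 iterations maximum,
convergence after 50 iterations of stable exemplars, damping 0.95, shared
preference = median of the **off-diagonal** similarities (the unit
self-similarities would bias a median over all entries). A seeded symmetric
jitter of magnitude `(max−min)·1e-12` breaks exact degeneracies while being
far below similarity resolution, so runs are reproducible bit-for-bit given
the seed. If message passing does not converge the genes are returned as
singleton clusters with `converged=False` and a warning — a deliberate,
visible failure mode rather than a silent partial answer.

Heavy damping converges slowly: on matrices with large blocks of near-equal
similarities the exemplar set can sit still for 50 iterations while the
messages are still in transit, so the run can stop before the structure
fully emerges. This is a property of the algorithm under these settings, not
of the implementation; the synthetic generator avoids manufacturing such
degeneracies (below).

## Evaluation protocol

Noise injection selects `round_half_up(fraction × pathway size)` outsider
genes (0.5 × 10 = 5), uniformly from the pool or, in EC-matched mode,
restricted per reference cluster to pool genes whose first two EC levels
match a member of that cluster, with per-cluster quotas proportional to
cluster size and the remainder assigned to the largest cluster. Scoring
appends the noise genes to the reference as one extra cluster, then counts,
for each gene against every other gene, co-membership agreement between
reference and prediction (TP/TN/FP/FN summing to n−1 per gene), condenses
each gene's counts into an MCC (zero denominator → 0, the standard
convention), averages genes within each reference cluster and clusters into
the overall score.

Pair samplers (uniform pairs with an optional constant-weight-similarity
threshold, and same-depth sibling pairs) verify their own outputs by
predicate recomputation in the tests. Depth is the minimum edge count from
the namespace root (root = 0), the common convention; both members of a
sibling pair must sit at the requested depth.

## Synthetic study conditions

The fixture generator grows a single-rooted, single-namespace DAG of 120
terms (depth ≤ 6, mean branching ≈ 3, 80/20 `is_a`/`part_of`, second
parents with probability 0.15 — parents are always already-created shallower
terms, so acyclicity holds by construction). Planted gene sets emulate the
scale of the SGD pathways used for clustering evaluation: 12 genes in 3
clusters (the tryptophan-degradation pathway has 11 genes in 3 enzyme
groups), 3–6 terms per gene. Each cluster owns a disjoint "home" pool — the
exclusive part of one subtree, carved smallest-sufficient-first so pools are
tight and mutually disentangled — and a gene draws each term from its home
pool with probability `within_cluster_term_overlap`, uniformly from the
whole namespace otherwise. Pools must hold at least twice the per-gene term
maximum: with smaller pools, fully-overlapping genes would receive
*identical* term sets, producing duplicate similarity rows that no real
pathway exhibits and that stall heavily-damped affinity propagation on
degenerate plateaus. Clusters share the first two EC levels (distinct across
clusters) so EC-matched noise selection is exercisable; a separate noise
pool draws terms uniformly.

What passing on these fixtures shows: the propagation arithmetic, mixing
algebra, clustering configuration and scoring protocol are correct, and the
whole pipeline separates planted structure whose strength is controlled.
What it does not show: performance on the real GO (scale, shared ancestry
across subtrees, annotation bias) — the checks against the archived
2016-09-10 release cover the term-level arithmetic there, and require the
user to supply that release under `data/`.

## Problem sizes

The test suite checks the propagation against exhaustive path enumeration on
500 random DAGs of 5–30 terms (tolerance 1e-12) and runs the full recovery
pipeline at four overlap levels × 10 seeds; the acceptance script uses 100
enumeration DAGs, 10 recovery seeds per overlap level, a 200-term ontology
for the IC correlation and 100 sampled pairs for the method-agreement
statistic. These sizes give stable statistics at interactive runtimes.

## Known limitations

* The synthetic DAGs do not model GO's degree distribution or the density of
  multi-parent terms; correlations measured on them (e.g. children-count vs
  IC, method agreement) are qualitative analogues of the real-corpus values,
  not estimates of them.
* OBO parsing targets OBO 1.2 as distributed in GO releases; OWL and
  ontology editing are out of scope, as is fetching releases.
* GAF dialects 2.0–2.2 are accepted by header sniffing; unknown versions are
  parsed as 2.1.
* The regulates-aware variant retains `regulates` edges only where the
  release defines them (BPO/MFO); similarity values are otherwise identical
  to the default variant.
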