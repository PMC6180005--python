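# gogosim

Topology-based semantic similarity between Gene Ontology (GO) terms, gene
functional similarity, affinity-propagation gene clustering, and MCC-based
evaluation against reference pathways.

## The problem

Quantifying how similar two GO terms are underpins gene clustering, protein
function evaluation and interaction validation. Information-content (IC)
methods (Resnik, Lin) score terms by corpus statistics, which makes them
corpus-dependent and expensive to prepare; pure topology methods with
constant edge weights (Wang's measure) are stable but blind to how generic
an ancestor is. This package implements a hybrid: edge weights on the GO DAG
that shrink with the number of children of the ancestor term, exploiting the
strong negative correlation between a term's children count and its IC. The
measure needs no annotation corpus yet behaves like an IC-aware one.

## The measure

For a term *A*, let DAG_A = (A, T_A, E_A) be *A* together with its ancestors
and the typed edges among them (`is_a`, `part_of`, optionally `regulates`).
Crossing an edge into ancestor *t* carries weight

    w_e = 1 / (c + nc(t)) + d

with `nc(t)` the number of direct children of *t* in the full ontology,
`d` = 0.4 / 0.3 / 0.2 for `is_a` / `part_of` / `regulates`, and `c` ≥ 0.67
(default 0.67) so that 0 < w_e ≤ 1. Each ancestor's S-value is the best
descending path product,

    S_A(A) = 1,   S_A(t) = max { w_e · S_A(t') : t' ∈ children(t) ∩ T_A },

the semantic value is SV(A) = Σ_{t∈T_A} S_A(t), and two terms are compared by

    S_GO(A, B) = Σ_{t ∈ T_A ∩ T_B} (S_A(t) + S_B(t)) / (SV(A) + SV(B)).

Setting the edge weight to a constant per relation (0.8 / 0.6) instead
recovers Wang's measure, available as a baseline, alongside corpus-based
Resnik and Lin.

Gene-level similarity mixes the pairwise term similarities of two genes'
annotation sets with one of five strategies (`Avg`, `Max`, `ABM`, `BMA`,
`BMM`; default `ABM`, the pooled best-match average). Gene lists are
clustered by affinity propagation (500 iterations, convergence after 50
stable iterations, damping 0.95, preference = median pairwise similarity)
and clusterings are scored against reference pathways with per-gene Matthews
correlation coefficients over pairwise co-membership, optionally after
injecting outsider "noise" genes (random or EC-number-matched).

## Worked example

```python
import gogosim as g

spec = g.FixtureSpec(seed=5, within_cluster_term_overlap=1.0)
ont = g.generate_ontology(spec)                 # 120-term synthetic GO-like DAG
ann, ref = g.generate_clustered_genes(spec, ont)  # 12 genes in 3 planted clusters

sim = g.TermSimilarityProvider(ont, g.SemSimConfig.gogo())
print(round(sim("GO:9000053", "GO:9000034"), 3))   # 0.857

matrix = g.pairwise_gene_matrix(ont, ann, ann.genes)
assign = g.affinity_propagation(matrix, g.APConfig(seed=5))
print(g.evaluate_clustering(assign, ref).overall)  # 1.0
```

The term similarity 0.857 says the two terms share most of their ancestor
S-mass; the overall MCC of 1.0 says affinity propagation recovered the three
planted clusters exactly. The same pipeline from the shell:

```bash
gogosim simulate --outdir demo --seed 5 --overlap 1.0
gogosim cluster --obo demo/ontology.obo --annotations demo/genes.tsv \
    --reference demo/pathway.tsv --seed 5
```

prints the gene/cluster/exemplar table and, to stderr,

```json
{"overall_mcc": 1.0, "per_cluster_mcc": {"cluster0": 1.0, "cluster1": 1.0, "cluster2": 1.0}}
```

Other subcommands: `term-sim` (batch term pairs), `gene-sim` (pairwise gene
matrix), `ic` (corpus IC table and children-count correlation), `benchmark`
(pair sampling and method correlations).

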