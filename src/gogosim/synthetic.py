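"""Seeded synthetic ontologies, annotation sets and reference pathways.

Every downstream operation — parsing, S-value propagation, IC, gene
similarity, clustering, MCC evaluation — is testable on these fixtures
without downloading a GO release.  The ontology generator grows a rooted,
single-namespace DAG by attaching each new term under already-created
shallower terms (acyclic by construction); the gene generator plants
reference clusters by giving each cluster a disjoint "home" subtree and
drawing most of a gene's terms from its home (the rest uniformly), so the
planted structure's strength is a single dial (the within-cluster term
overlap).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import networkx as nx

from .evaluation import ReferencePathway
from .ontology import NAMESPACE_CODES, AnnotationSet, OntologyGraph


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study condition.

    ``branching`` is the target mean number of children per non-leaf term;
    ``relation_mix`` gives the probability of each relation type on a new
    edge; ``within_cluster_term_overlap`` is the probability that a gene's
    term is drawn from its cluster's home subtree rather than uniformly;
    ``extra_parent_rate`` is the chance a term gets a second parent (making
    the graph a proper DAG rather than a tree).
    """

    n_terms: int = 120
    max_depth: int = 6
    branching: float = 3.0
    relation_mix: tuple[tuple[str, float], ...] = (
        ("is_a", 0.8), ("part_of", 0.2), ("regulates", 0.0))
    n_genes: int = 12
    terms_per_gene: tuple[int, int] = (3, 6)
    n_clusters: int = 3
    within_cluster_term_overlap: float = 0.9
    seed: int = 0
    extra_parent_rate: float = 0.15
    namespace: str = "biological_process"

    def __post_init__(self) -> None:
        probs = [p for _, p in self.relation_mix]
        if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
            raise ValueError("relation_mix probabilities must be non-negative and sum to 1")
        if not (self.n_terms >= self.n_clusters >= 1):
            raise ValueError("need n_terms ≥ n_clusters ≥ 1")
        if self.namespace not in NAMESPACE_CODES:
            raise ValueError(f"unknown namespace {self.namespace!r}")
        lo, hi = self.terms_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("terms_per_gene must be a range of positive integers")
        if not 0.0 <= self.within_cluster_term_overlap <= 1.0:
            raise ValueError("within_cluster_term_overlap must be in [0, 1]")
        if self.n_terms > 1 and (self.max_depth < 1 or self.branching <= 0):
            raise ValueError(
                f"infeasible spec: {self.n_terms} terms cannot fit max_depth="
                f"{self.max_depth} with branching={self.branching}")


def _term_id(i: int) -> str:
    return f"GO:9{i:06d}"


def generate_ontology(spec: FixtureSpec) -> OntologyGraph:
    """Grow a seeded single-root DAG of ``spec.n_terms`` terms.

    Each new term takes a primary parent among existing terms of depth
    < max_depth (preferring terms with fewer children, so the mean number of
    children tracks ``spec.branching``) and, with probability
    ``extra_parent_rate``, one extra strictly shallower parent.  Relation
    types are drawn from ``relation_mix``.
    """
    rng = np.random.default_rng(spec.seed)
    rels = [r for r, _ in spec.relation_mix]
    rel_p = np.array([p for _, p in spec.relation_mix])

    ns_code = NAMESPACE_CODES[spec.namespace]
    g = nx.MultiDiGraph()
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    depth: dict[str, int] = {}
    n_children: dict[str, int] = {}

    root = _term_id(0)
    g.add_node(root)
    names[root] = "synthetic root"
    namespaces[root] = ns_code
    depth[root] = 0
    n_children[root] = 0

    order: list[str] = [root]
    for i in range(1, spec.n_terms):
        term = _term_id(i)
        candidates = [t for t in order if depth[t] < spec.max_depth]
        if not candidates:
            raise ValueError(f"infeasible spec: no parent below max_depth for term {i}")
        weights = np.array([math.exp(-n_children[t] / spec.branching) for t in candidates])
        weights /= weights.sum()
        primary = candidates[int(rng.choice(len(candidates), p=weights))]
        rel = rels[int(rng.choice(len(rels), p=rel_p))]
        g.add_node(term)
        g.add_edge(term, primary, key=rel)
        names[term] = f"synthetic term {i}"
        namespaces[term] = ns_code
        depth[term] = depth[primary] + 1
        n_children[term] = 0
        n_children[primary] += 1
        if rng.random() < spec.extra_parent_rate:
            shallower = [t for t in order if depth[t] < depth[term] and t != primary]
            if shallower:
                extra = shallower[int(rng.choice(len(shallower)))]
                xrel = rels[int(rng.choice(len(rels), p=rel_p))]
                if not g.has_edge(term, extra, key=xrel):
                    g.add_edge(term, extra, key=xrel)
                    n_children[extra] += 1
        order.append(term)

    ont = OntologyGraph(graph=g, names=names, namespaces=namespaces,
                        release_date=f"synthetic-seed-{spec.seed}")
    ont.validate()
    return ont


def _home_pools(spec: FixtureSpec, ontology: OntologyGraph) -> list[list[str]]:
    """Disjoint per-cluster term pools, each the exclusive part of one subtree.

    Candidate seeds (any non-root term) are taken smallest-sufficient-subtree
    first — small subtrees are tight (their terms share close ancestry) and
    rarely entangled with each other; a seed founds a pool only if enough of
    its subtree is not already claimed, so overlap = 1 genes never share
    terms across clusters.
    """
    ns = NAMESPACE_CODES[spec.namespace]
    roots = ontology.roots(ns)
    candidates = sorted(set(ontology.graph.nodes) - roots)
    if len(candidates) < spec.n_clusters:
        raise ValueError(
            f"only {len(candidates)} non-root terms; cannot plant {spec.n_clusters} clusters")
    subtree = {t: ontology.descendants(t) | {t} for t in candidates}
    lo, hi = spec.terms_per_gene
    # Pools hold at least twice the per-gene maximum so same-cluster genes get
    # distinct (if heavily overlapping) term sets, as real pathway members do;
    # duplicate annotation profiles would make the similarity matrix degenerate.
    min_pool = 2 * hi
    pools: list[list[str]] = []
    used: set[str] = set()
    for seed in sorted(candidates, key=lambda t: (len(subtree[t]), t)):
        if len(pools) == spec.n_clusters:
            break
        if len(subtree[seed]) < min_pool:
            continue
        exclusive = sorted(subtree[seed] - used)
        if len(exclusive) < min_pool:
            continue  # too entangled with earlier pools to host a cluster
        pools.append(exclusive)
        used.update(exclusive)
    if len(pools) < spec.n_clusters:
        raise ValueError(
            f"could not carve {spec.n_clusters} disjoint home subtrees with ≥ {min_pool} "
            f"terms each (overlap incompatible with subtree sizes)")
    return pools


def generate_clustered_genes(spec: FixtureSpec, ontology: OntologyGraph,
                             ) -> tuple[AnnotationSet, ReferencePathway]:
    """Plant ``n_clusters`` gene groups with semantically coherent annotations.

    Genes are spread round-robin over clusters; each gene draws its terms
    from its cluster's home pool with probability ``within_cluster_term_overlap``
    and uniformly from the whole namespace otherwise.  Clusters share the
    first two EC levels (distinct across clusters) so EC-matched noise
    selection is testable.
    """
    rng = np.random.default_rng(spec.seed + 1)
    pools = _home_pools(spec, ontology)
    all_terms = sorted(ontology.graph.nodes)
    ns_code = NAMESPACE_CODES[spec.namespace]
    lo, hi = spec.terms_per_gene

    records: dict[str, set[tuple[str, str, str]]] = {}
    labels: dict[str, str] = {}
    ec: dict[str, str] = {}
    for gi in range(spec.n_genes):
        c = gi % spec.n_clusters
        gene = f"G{c}_{gi:03d}"
        k = int(rng.integers(lo, hi + 1))
        terms: set[str] = set()
        guard = 0
        while len(terms) < k and guard < 200:
            guard += 1
            if rng.random() < spec.within_cluster_term_overlap:
                pool = pools[c]
            else:
                pool = all_terms
            terms.add(pool[int(rng.choice(len(pool)))])
        records[gene] = {(t, "IDA", ns_code) for t in terms}
        labels[gene] = f"cluster{c}"
        ec[gene] = f"{c + 1}.{(c % 9) + 1}.{gi + 1}.{gi + 1}"

    annotations = AnnotationSet(records=records)
    reference = ReferencePathway(labels=labels, ec=ec)
    return annotations, reference


def generate_noise_pool(spec: FixtureSpec, ontology: OntologyGraph, n_pool: int = 30,
                        seed_offset: int = 1000) -> tuple[AnnotationSet, dict[str, str]]:
    """Outsider genes (uniform random annotations) with EC numbers spanning the
    clusters' top-two-level EC classes, for noise-injection experiments."""
    rng = np.random.default_rng(spec.seed + seed_offset)
    all_terms = sorted(ontology.graph.nodes)
    ns_code = NAMESPACE_CODES[spec.namespace]
    lo, hi = spec.terms_per_gene
    records: dict[str, set[tuple[str, str, str]]] = {}
    ec_map: dict[str, str] = {}
    for i in range(n_pool):
        gene = f"N_{i:03d}"
        k = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(all_terms), size=min(k, len(all_terms)), replace=False)
        records[gene] = {(all_terms[j], "IDA", ns_code) for j in idx.tolist()}
        c = i % spec.n_clusters
        ec_map[gene] = f"{c + 1}.{(c % 9) + 1}.{90 + i}.{i + 1}"
    return AnnotationSet(records=records), ec_map
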