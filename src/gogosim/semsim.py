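"""Children-count-aware semantic similarity between GO terms.

The measure propagates a *semantic contribution* (S-value) from a query term
A up through its ancestor DAG.  Crossing an edge into an ancestor ``t``
multiplies the contribution by an edge weight

    w_e = 1 / (c + nc(t)) + d

where ``nc(t)`` is the number of direct children of ``t`` in the **full**
ontology under the configured relation set, ``d`` depends on the relation
type (0.4 ``is_a``, 0.3 ``part_of``, 0.2 ``regulates``) and ``c`` is a
constant (default 0.67, the smallest value that keeps every weight in
(0, 1] given d ≤ 0.4 and nc ≥ 1).  Ancestors with many children — which in
annotation corpora carry low information content — therefore contribute
less, giving the topology-only measure an IC-like flavour without needing a
corpus.  Setting the edge weight to a per-relation constant instead (0.8
``is_a`` / 0.6 ``part_of``) recovers Wang's measure, which this module also
provides as a baseline.

The S-value of an ancestor is the maximum, over descending paths from the
ancestor to A, of the product of edge weights.  Two terms are compared by
pooling the S-values of their shared ancestors, normalised by the summed
S-values (semantic values) of each term's own ancestor DAG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .ontology import RELATIONS, OntologyGraph, TermLookupError


class ConfigError(ValueError):
    """Invalid similarity configuration (weights would leave (0, 1])."""


#: Minimum safe value of c: with d = 0.4 and nc = 1, w = 1/(c+1) + 0.4 ≤ 1 ⟺ c ≥ 2/3.
MIN_C = 0.67

_DEFAULT_D = (("is_a", 0.4), ("part_of", 0.3), ("regulates", 0.2))
_DEFAULT_WANG = (("is_a", 0.8), ("part_of", 0.6), ("regulates", 0.6))


@dataclass(frozen=True)
class SemSimConfig:
    """Configuration of the term-similarity measure.

    ``method`` selects children-count weighting (``"gogo"``) or constant
    per-relation weights (``"wang"``).  ``relations`` is the edge subset used
    for ancestor traversal and children counting; the default omits
    ``regulates``, matching the primary method variant, while
    :meth:`gogo_regulates` includes it.
    """

    method: str = "gogo"
    c: float = 0.67
    relations: tuple[str, ...] = ("is_a", "part_of")
    d_weights: tuple[tuple[str, float], ...] = _DEFAULT_D
    wang_weights: tuple[tuple[str, float], ...] = _DEFAULT_WANG
    cross_namespace: bool = False
    allow_unsafe_c: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("gogo", "wang"):
            raise ConfigError(f"unknown method {self.method!r}")
        unknown = set(self.relations) - set(RELATIONS)
        if unknown:
            raise ConfigError(f"unsupported relations: {sorted(unknown)}")
        if not self.relations:
            raise ConfigError("at least one relation type is required")
        if self.c < MIN_C and not self.allow_unsafe_c:
            raise ConfigError(
                f"c = {self.c} < {MIN_C} can push edge weights above 1 "
                "(set allow_unsafe_c=True to override)")
        if self.c <= 0:
            raise ConfigError("c must be positive")
        for name, table in (("d_weights", self.d_weights), ("wang_weights", self.wang_weights)):
            for rel, w in table:
                if not 0.0 < w < 1.0:
                    raise ConfigError(f"{name}[{rel}] = {w} outside (0, 1)")

    # weight lookups -----------------------------------------------------

    def d(self, relation: str) -> float:
        for rel, w in self.d_weights:
            if rel == relation:
                return w
        raise ConfigError(f"no d weight configured for relation {relation!r}")

    def wang_weight(self, relation: str) -> float:
        for rel, w in self.wang_weights:
            if rel == relation:
                return w
        raise ConfigError(f"no Wang weight configured for relation {relation!r}")

    # common variants ----------------------------------------------------

    @classmethod
    def gogo(cls, **kw) -> "SemSimConfig":
        return cls(method="gogo", relations=("is_a", "part_of"), **kw)

    @classmethod
    def gogo_regulates(cls, **kw) -> "SemSimConfig":
        return cls(method="gogo", relations=("is_a", "part_of", "regulates"), **kw)

    @classmethod
    def wang(cls, **kw) -> "SemSimConfig":
        kw.setdefault("relations", ("is_a", "part_of"))
        return cls(method="wang", **kw)


@dataclass
class AncestorGraph:
    """A term, its ancestor closure, the edges among them, and the S-values."""

    target: str
    node_set: frozenset[str]
    edge_set: frozenset[tuple[str, str, str]]  # (child, parent, relation)
    s_values: dict[str, float]

    def semantic_value(self) -> float:
        return sum(self.s_values.values())


def children_count(ontology: OntologyGraph, term: str,
                   relations: Iterable[str] = ("is_a", "part_of")) -> int:
    """Number of distinct direct children of ``term`` in the full ontology."""
    return len(ontology.children(term, relations))


def edge_weight(ontology: OntologyGraph, parent: str, relation: str,
                config: SemSimConfig) -> float:
    """Weight of the semantic contribution crossing an edge into ``parent``.

    Children-count mode: ``1/(c + nc(parent)) + d(relation)``; Wang mode: the
    configured per-relation constant.
    """
    if relation not in config.relations:
        raise ConfigError(f"relation {relation!r} not in configured set {config.relations}")
    if config.method == "wang":
        w = config.wang_weight(relation)
    else:
        nc = children_count(ontology, parent, config.relations)
        w = 1.0 / (config.c + nc) + config.d(relation)
    if not 0.0 < w <= 1.0:
        raise ConfigError(
            f"edge weight {w:.4f} for parent {parent} (relation {relation}) "
            "falls outside (0, 1]; check c and d settings")
    return w


def build_ancestor_graph(ontology: OntologyGraph, term: str,
                         config: SemSimConfig | None = None) -> AncestorGraph:
    """Upward closure of ``term`` with S-values from max-product propagation.

    S(term) = 1; for each proper ancestor ``t``, S(t) is the maximum over
    children ``t'`` of ``t`` *inside the closure* of
    ``edge_weight(t, relation) × S(t')`` — equivalently the best descending
    weight-product path from ``t`` down to the query term.  Edge weights use
    the children count of the ancestor in the full ontology.
    """
    config = config or SemSimConfig()
    target = ontology.resolve(term)

    ns = ontology.namespaces[target]
    nodes: set[str] = {target}
    edges: set[tuple[str, str, str]] = set()
    stack = [target]
    while stack:
        node = stack.pop()
        for parent, rel in ontology.parents(node, config.relations):
            if not config.cross_namespace and ontology.namespaces[parent] != ns:
                continue
            edges.add((node, parent, rel))
            if parent not in nodes:
                nodes.add(parent)
                stack.append(parent)

    # child → parent edges: topological order yields children before parents.
    dag = nx.DiGraph()
    dag.add_nodes_from(nodes)
    dag.add_edges_from((c, p) for c, p, _ in edges)
    s: dict[str, float] = {}
    for t in nx.topological_sort(dag):
        if t == target:
            s[t] = 1.0
            continue
        best = 0.0
        for child, parent, rel in edges:
            if parent != t:
                continue
            w = edge_weight(ontology, t, rel, config)
            cand = w * s[child]
            if cand > best:
                best = cand
        s[t] = best

    return AncestorGraph(
        target=target,
        node_set=frozenset(nodes),
        edge_set=frozenset(edges),
        s_values=s,
    )


def semantic_value(g: AncestorGraph) -> float:
    """Sum of S-values over the ancestor closure; ≥ 1, = 1 only at a root."""
    return g.semantic_value()


def term_similarity(ontology: OntologyGraph, a: str, b: str,
                    config: SemSimConfig | None = None,
                    _cache: Mapping[str, AncestorGraph] | None = None) -> float:
    """Similarity of two terms: pooled shared-ancestor S-values over summed
    semantic values.  Symmetric, 1 for identical terms, 0 only for
    ancestor-disjoint pairs."""
    config = config or SemSimConfig()
    a = ontology.resolve(a)
    b = ontology.resolve(b)
    if not config.cross_namespace and ontology.namespaces[a] != ontology.namespaces[b]:
        raise ValueError(
            f"terms {a} ({ontology.namespaces[a]}) and {b} ({ontology.namespaces[b]}) "
            "are in different namespaces; set cross_namespace=True to allow")
    if _cache is not None and a in _cache:
        ga = _cache[a]
    else:
        ga = build_ancestor_graph(ontology, a, config)
    if _cache is not None and b in _cache:
        gb = _cache[b]
    else:
        gb = build_ancestor_graph(ontology, b, config)
    common = ga.node_set & gb.node_set
    if not common:
        return 0.0
    num = sum(ga.s_values[t] + gb.s_values[t] for t in common)
    return num / (ga.semantic_value() + gb.semantic_value())


class TermSimilarityProvider:
    """Memoizing term-similarity callable bound to one ontology and config.

    Gene-level similarity recomputes many term pairs over a small term pool;
    caching the ancestor graphs (per term) and pair values makes that cheap.
    Caching cannot change results — it only reuses the deterministic
    AncestorGraph of each term.
    """

    def __init__(self, ontology: OntologyGraph, config: SemSimConfig | None = None):
        self.ontology = ontology
        self.config = config or SemSimConfig()
        self._graphs: dict[str, AncestorGraph] = {}
        self._pairs: dict[tuple[str, str], float] = {}

    def ancestor_graph(self, term: str) -> AncestorGraph:
        term = self.ontology.resolve(term)
        g = self._graphs.get(term)
        if g is None:
            g = build_ancestor_graph(self.ontology, term, self.config)
            self._graphs[term] = g
        return g

    def __call__(self, a: str, b: str) -> float:
        a = self.ontology.resolve(a)
        b = self.ontology.resolve(b)
        key = (a, b) if a <= b else (b, a)
        val = self._pairs.get(key)
        if val is None:
            self.ancestor_graph(a)
            self.ancestor_graph(b)
            val = term_similarity(self.ontology, a, b, self.config, _cache=self._graphs)
            self._pairs[key] = val
        return val
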