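"""Reading and validating GO ontologies (OBO 1.2) and gene annotations (GAF / TSV).

The Gene Ontology is distributed as three rooted DAGs — biological process
(BPO), cellular component (CCO) and molecular function (MFO) — whose edges
carry typed relations (``is_a``, ``part_of``, ``regulates``).  This module
loads an OBO release into an :class:`OntologyGraph` (a typed child→parent
multigraph with alt-ID and obsolete-term bookkeeping) and loads gene→term
annotations from GAF 2.x or a simple two/three-column TSV into an
:class:`AnnotationSet`.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Relation types understood by the similarity machinery.
RELATIONS = ("is_a", "part_of", "regulates")

#: Sub-relations collapsed onto plain ``regulates`` (they share one contribution weight).
_REGULATES_SUBTYPES = frozenset({"regulates", "positively_regulates", "negatively_regulates"})

#: OBO namespace string -> short ontology code.
NAMESPACE_CODES = {
    "biological_process": "BPO",
    "cellular_component": "CCO",
    "molecular_function": "MFO",
}
_CODE_TO_NAMESPACE = {v: k for k, v in NAMESPACE_CODES.items()}

#: Experimental evidence codes (the only ones used for the pathway evaluations).
EXPERIMENTAL_EVIDENCE = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})


class OntologyError(Exception):
    """Base class for ontology/annotation handling failures."""


class OboParseError(OntologyError):
    """Malformed OBO input; the message names the offending line."""


class ValidationError(OntologyError):
    """A structural invariant of the ontology graph is violated."""


class TermLookupError(OntologyError, KeyError):
    """A term identifier does not resolve to a primary, non-obsolete term."""


class AnnotationParseError(OntologyError):
    """Malformed annotation input; the message names the offending line."""


def _normalize_relation(relation: str) -> str | None:
    if relation == "is_a" or relation == "part_of":
        return relation
    if relation in _REGULATES_SUBTYPES:
        return "regulates"
    return None


@dataclass
class OntologyGraph:
    """A typed GO DAG: nodes are primary term IDs, edges run child → parent.

    ``graph`` is a :class:`networkx.MultiDiGraph` whose edge keys are relation
    types.  Alternative identifiers map onto their primary IDs and obsolete
    identifiers are recorded but excluded from the graph.
    """

    graph: nx.MultiDiGraph
    names: dict[str, str]
    namespaces: dict[str, str]  # term -> BPO|CCO|MFO
    alt_id_map: dict[str, str] = field(default_factory=dict)
    obsolete_ids: set[str] = field(default_factory=set)
    release_date: str = ""

    # -- lookup ---------------------------------------------------------------

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph or term in self.alt_id_map

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def resolve(self, term: str) -> str:
        """Map a (possibly alternative) identifier onto its primary term ID."""
        if term in self.graph:
            return term
        if term in self.alt_id_map:
            return self.alt_id_map[term]
        if term in self.obsolete_ids:
            raise TermLookupError(f"term {term} is obsolete in this release")
        raise TermLookupError(f"unknown term identifier {term}")

    def namespace_of(self, term: str) -> str:
        return self.namespaces[self.resolve(term)]

    def name_of(self, term: str) -> str:
        return self.names.get(self.resolve(term), "")

    # -- topology -------------------------------------------------------------

    def parents(self, term: str, relations: Iterable[str] | None = None) -> list[tuple[str, str]]:
        """(parent, relation) pairs for the direct parents of ``term``."""
        term = self.resolve(term)
        wanted = None if relations is None else frozenset(relations)
        out = []
        for _, parent, rel in self.graph.out_edges(term, keys=True):
            if wanted is None or rel in wanted:
                out.append((parent, rel))
        return out

    def children(self, term: str, relations: Iterable[str] | None = None) -> set[str]:
        """Distinct direct children of ``term`` under the given relation types."""
        term = self.resolve(term)
        wanted = None if relations is None else frozenset(relations)
        return {
            child
            for child, _, rel in self.graph.in_edges(term, keys=True)
            if wanted is None or rel in wanted
        }

    def ancestors(self, term: str, relations: Iterable[str] | None = None,
                  same_namespace: bool = True) -> set[str]:
        """All terms reachable upward from ``term`` (excluding ``term`` itself)."""
        term = self.resolve(term)
        ns = self.namespaces[term]
        wanted = None if relations is None else frozenset(relations)
        seen: set[str] = set()
        stack = [term]
        while stack:
            node = stack.pop()
            for _, parent, rel in self.graph.out_edges(node, keys=True):
                if wanted is not None and rel not in wanted:
                    continue
                if same_namespace and self.namespaces[parent] != ns:
                    continue
                if parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
        return seen

    def descendants(self, term: str, relations: Iterable[str] | None = None,
                    same_namespace: bool = True) -> set[str]:
        """All terms reaching ``term`` via upward edges (excluding ``term``)."""
        term = self.resolve(term)
        ns = self.namespaces[term]
        wanted = None if relations is None else frozenset(relations)
        seen: set[str] = set()
        stack = [term]
        while stack:
            node = stack.pop()
            for child, _, rel in self.graph.in_edges(node, keys=True):
                if wanted is not None and rel not in wanted:
                    continue
                if same_namespace and self.namespaces[child] != ns:
                    continue
                if child not in seen:
                    seen.add(child)
                    stack.append(child)
        return seen

    def roots(self, namespace: str) -> set[str]:
        """Terms of ``namespace`` with no parent inside that namespace."""
        out = set()
        for term, ns in self.namespaces.items():
            if ns != namespace:
                continue
            ps = [p for p, _ in self.parents(term) if self.namespaces[p] == ns]
            if not ps:
                out.add(term)
        return out

    def restricted(self, relations: Iterable[str]) -> "OntologyGraph":
        """A copy whose edge set is restricted to ``relations`` (same terms)."""
        wanted = frozenset(relations)
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.graph.nodes)
        for child, parent, rel in self.graph.edges(keys=True):
            if rel in wanted:
                g.add_edge(child, parent, key=rel)
        return OntologyGraph(
            graph=g,
            names=dict(self.names),
            namespaces=dict(self.namespaces),
            alt_id_map=dict(self.alt_id_map),
            obsolete_ids=set(self.obsolete_ids),
            release_date=self.release_date,
        )

    def edge_set(self) -> set[tuple[str, str, str]]:
        return {(c, p, r) for c, p, r in self.graph.edges(keys=True)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OntologyGraph):
            return NotImplemented
        return (
            self.terms == other.terms
            and self.edge_set() == other.edge_set()
            and self.namespaces == other.namespaces
            and self.alt_id_map == other.alt_id_map
            and self.obsolete_ids == other.obsolete_ids
        )

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`ValidationError` on failure."""
        for child, parent, rel in self.graph.edges(keys=True):
            if rel not in RELATIONS:
                raise ValidationError(f"edge {child}->{parent} has unknown relation {rel!r}")
            for endpoint in (child, parent):
                if endpoint in self.obsolete_ids:
                    raise ValidationError(f"edge endpoint {endpoint} is obsolete")
        for alt, primary in self.alt_id_map.items():
            if primary not in self.graph:
                raise ValidationError(f"alt_id {alt} maps to unknown primary {primary}")
        for term in self.graph.nodes:
            if term not in self.namespaces:
                raise ValidationError(f"term {term} has no namespace")
        plain = nx.DiGraph(self.graph)
        if not nx.is_directed_acyclic_graph(plain):
            cycle = nx.find_cycle(plain)
            raise ValidationError(f"relation graph contains a cycle: {cycle}")


# -- OBO reading / writing ----------------------------------------------------


def _prevalidate_obo(text: str) -> None:
    """Cheap line-level scan so parse errors can name the offending line."""
    in_term = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("["):
            if not line.endswith("]"):
                raise OboParseError(f"line {lineno}: malformed stanza header {line!r}")
            in_term = line == "[Term]"
            continue
        if in_term:
            tag, sep, _ = line.partition(":")
            if not sep or any(ch.isspace() for ch in tag):
                raise OboParseError(f"line {lineno}: expected 'tag: value', got {line!r}")


def parse_obo(source: str | IO[str], relations: Iterable[str] = ("is_a", "part_of"),
              default_namespace: str | None = None) -> OntologyGraph:
    """Parse OBO 1.2 text into an :class:`OntologyGraph`.

    Parameters
    ----------
    source:
        A path, OBO text, or an open text stream.
    relations:
        Relation subset to retain; ``regulates`` implies its positive/negative
        sub-relations, which are collapsed onto a single ``regulates`` type.
    default_namespace:
        Namespace assumed for stanzas without one (OBO ``default-namespace``
        header takes precedence).
    """
    wanted = frozenset(relations)
    unknown = wanted - set(RELATIONS)
    if unknown:
        raise ValueError(f"unsupported relations: {sorted(unknown)}")

    if hasattr(source, "read"):
        text = source.read()
    elif "\n" in source or source.lstrip().startswith(("format-version", "[Term]", "!")):
        text = source
    else:
        with open(source, "rt", encoding="utf-8") as fh:
            text = fh.read()

    _prevalidate_obo(text)
    try:
        multi = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    except Exception as exc:  # pragma: no cover - obonet is permissive
        raise OboParseError(f"unparseable OBO input: {exc}") from exc

    header_default = multi.graph.get("default-namespace")
    if isinstance(header_default, list):
        header_default = header_default[0] if header_default else None
    fallback_ns = header_default or default_namespace

    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    alt_id_map: dict[str, str] = {}
    obsolete: set[str] = set()
    primary: set[str] = set()

    for term, attrs in multi.nodes(data=True):
        if str(attrs.get("is_obsolete", "")).lower() == "true":
            obsolete.add(term)
            continue
        ns_long = attrs.get("namespace", fallback_ns)
        if ns_long is None:
            raise OboParseError(f"term {term} has no namespace and no default is set")
        code = NAMESPACE_CODES.get(ns_long)
        if code is None:
            raise OboParseError(f"term {term} has unknown namespace {ns_long!r}")
        primary.add(term)
        names[term] = attrs.get("name", "")
        namespaces[term] = code
        for alt in attrs.get("alt_id", []):
            alt_id_map[alt] = term

    g = nx.MultiDiGraph()
    g.add_nodes_from(primary)
    for child, parent, rel in multi.edges(keys=True):
        norm = _normalize_relation(rel)
        if norm is None or norm not in wanted:
            continue
        if child not in primary or parent not in primary:
            continue  # edges touching obsolete stanzas are dropped
        g.add_edge(child, parent, key=norm)

    release = multi.graph.get("data-version") or multi.graph.get("date") or ""
    ont = OntologyGraph(
        graph=g,
        names=names,
        namespaces=namespaces,
        alt_id_map=alt_id_map,
        obsolete_ids=obsolete,
        release_date=release,
    )
    ont.validate()
    return ont


def write_obo(ontology: OntologyGraph) -> str:
    """Serialize an :class:`OntologyGraph` back to OBO 1.2 text.

    The output round-trips through :func:`parse_obo`: term set, typed edge
    set, namespaces, alt IDs and obsolete IDs are all preserved.
    """
    out = ["format-version: 1.2"]
    if ontology.release_date:
        out.append(f"data-version: {ontology.release_date}")
    out.append("ontology: go")
    out.append("")
    alt_by_primary: dict[str, list[str]] = {}
    for alt, prim in ontology.alt_id_map.items():
        alt_by_primary.setdefault(prim, []).append(alt)
    for term in sorted(ontology.graph.nodes):
        out.append("[Term]")
        out.append(f"id: {term}")
        out.append(f"name: {ontology.names.get(term, term)}")
        out.append(f"namespace: {_CODE_TO_NAMESPACE[ontology.namespaces[term]]}")
        for alt in sorted(alt_by_primary.get(term, [])):
            out.append(f"alt_id: {alt}")
        for _, parent, rel in sorted(ontology.graph.out_edges(term, keys=True)):
            if rel == "is_a":
                out.append(f"is_a: {parent}")
            else:
                out.append(f"relationship: {rel} {parent}")
        out.append("")
    for term in sorted(ontology.obsolete_ids):
        out.append("[Term]")
        out.append(f"id: {term}")
        out.append(f"name: obsolete {term}")
        out.append("is_obsolete: true")
        out.append("")
    return "\n".join(out)


# -- annotations --------------------------------------------------------------


@dataclass
class AnnotationSet:
    """Gene → annotated GO terms, each with an evidence code and namespace."""

    records: dict[str, set[tuple[str, str, str]]]  # gene -> {(term, evidence, ns)}
    evidence_filter: frozenset[str] | None = None
    n_dropped_unknown: int = 0
    n_dropped_evidence: int = 0

    @property
    def genes(self) -> list[str]:
        return sorted(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def terms_for(self, gene: str, namespace: str | None = None) -> list[str]:
        """Distinct annotated terms of ``gene``, optionally restricted to a namespace."""
        recs = self.records.get(gene, set())
        terms = {t for t, _, ns in recs if namespace is None or ns == namespace}
        return sorted(terms)

    def occurrences(self) -> Iterable[tuple[str, str, str]]:
        for recs in self.records.values():
            yield from recs


def _sniff_gaf(lines: list[str]) -> bool:
    for line in lines:
        if line.startswith("!"):
            return True
        return len(line.rstrip("\n").split("\t")) >= 15
    return False


def parse_annotations(source: str | IO[str], ontology: OntologyGraph,
                      evidence_filter: Iterable[str] | None = None) -> AnnotationSet:
    """Parse GAF 2.x or the simple TSV dialect into an :class:`AnnotationSet`.

    GAF rows with a ``NOT`` qualifier are dropped; rows failing the evidence
    filter are dropped; rows citing unknown terms are dropped with a logged
    warning count; alternative IDs are stored under their primary ID.

    The simple dialect is ``gene<TAB>GO:ID;GO:ID;…`` with an optional third
    evidence-code column.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif "\n" in source or "\t" in source:
        text = source
    else:
        with open(source, "rt", encoding="utf-8") as fh:
            text = fh.read()

    allowed = frozenset(evidence_filter) if evidence_filter else None
    lines = text.splitlines()
    is_gaf = _sniff_gaf(lines)

    gaf_version = "2.1"
    records: dict[str, set[tuple[str, str, str]]] = {}
    dropped = {"unknown": 0, "evidence": 0}

    def add(gene: str, term_id: str, evidence: str) -> None:
        if allowed is not None and evidence not in allowed:
            dropped["evidence"] += 1
            return
        try:
            primary = ontology.resolve(term_id)
        except TermLookupError:
            dropped["unknown"] += 1
            return
        ns = ontology.namespaces[primary]
        records.setdefault(gene, set()).add((primary, evidence, ns))

    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith("!"):
            if line.lower().startswith("!gaf-version:"):
                ver = line.split(":", 1)[1].strip()
                if ver not in {"2.0", "2.1", "2.2"}:
                    logger.warning("unknown GAF version %r; parsing as 2.1", ver)
                else:
                    gaf_version = ver
            continue
        cols = line.rstrip("\n").split("\t")
        if is_gaf:
            if len(cols) < 9:
                raise AnnotationParseError(
                    f"line {lineno}: GAF {gaf_version} row has {len(cols)} columns (<9)")
            gene, qualifier, term_id, evidence = cols[2], cols[3], cols[4], cols[6]
            if "NOT" in qualifier.split("|"):
                continue
            add(gene, term_id, evidence)
        else:
            if len(cols) < 2 or not cols[1].strip():
                raise AnnotationParseError(
                    f"line {lineno}: expected gene<TAB>GO:ID;… , got {line!r}")
            gene = cols[0].strip()
            evidence = cols[2].strip() if len(cols) > 2 and cols[2].strip() else ""
            for term_id in (t.strip() for t in cols[1].split(";") if t.strip()):
                add(gene, term_id, evidence)

    if dropped["unknown"]:
        logger.warning("dropped %d annotation rows citing unknown terms", dropped["unknown"])
    if not records:
        warnings.warn("annotation set is empty after filtering", stacklevel=2)
    return AnnotationSet(
        records=records,
        evidence_filter=allowed,
        n_dropped_unknown=dropped["unknown"],
        n_dropped_evidence=dropped["evidence"],
    )
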