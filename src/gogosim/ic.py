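"""Corpus-based information content and the Resnik/Lin baselines.

IC(f) = −log P(f), where P(f) is the share of annotation occurrences that
fall on f or any of its descendants, within f's namespace.  The module also
provides the children-count vs IC correlation analysis that motivates using
the number of children as a corpus-free stand-in for IC: terms with many
children tend to be generic and carry low IC, so the grouped average IC is
negatively correlated with the children count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .ontology import AnnotationSet, OntologyGraph
from .semsim import children_count


@dataclass
class CorpusCounts:
    """Raw and descendant-propagated annotation counts plus per-term IC.

    ``ic`` holds NaN for terms whose propagated count is zero ("undefined"
    rather than infinite); such terms are listed in ``undefined``.
    """

    raw_counts: dict[str, int]
    propagated_counts: dict[str, int]
    namespace_totals: dict[str, int]
    ic: dict[str, float]
    undefined: set[str] = field(default_factory=set)


def compute_ic(ontology: OntologyGraph, corpus: AnnotationSet,
               relations: Iterable[str] = ("is_a", "part_of")) -> CorpusCounts:
    """Count annotation occurrences, propagate them to ancestors, derive IC.

    Each (gene, term) annotation record counts one occurrence of its term.
    A term's propagated count is the summed raw count of the term and all its
    descendants (each descendant counted once).  The namespace total is the
    propagated count at the namespace root, so IC(root) = 0 whenever the
    namespace has any annotations.  Natural log is used throughout.
    """
    raw: dict[str, int] = {}
    for term, _ev, _ns in corpus.occurrences():
        primary = ontology.resolve(term)
        raw[primary] = raw.get(primary, 0) + 1

    prop: dict[str, int] = {t: 0 for t in ontology.graph.nodes}
    for term, count in raw.items():
        prop[term] += count
        for anc in ontology.ancestors(term, relations):
            prop[anc] += count

    totals: dict[str, int] = {}
    namespaces = sorted(set(ontology.namespaces.values()))
    for ns in namespaces:
        roots = ontology.roots(ns)
        total = sum(prop.get(r, 0) for r in roots)
        totals[ns] = total
        if total == 0:
            warnings.warn(f"no annotations in namespace {ns}; all its ICs are undefined",
                          stacklevel=2)

    ic: dict[str, float] = {}
    undefined: set[str] = set()
    for term in ontology.graph.nodes:
        ns = ontology.namespaces[term]
        total = totals[ns]
        p = prop[term] / total if total else 0.0
        if p <= 0.0:
            ic[term] = float("nan")
            undefined.add(term)
        else:
            ic[term] = -math.log(p)

    return CorpusCounts(raw_counts=raw, propagated_counts=prop,
                        namespace_totals=totals, ic=ic, undefined=undefined)


def _common_ancestors(ontology: OntologyGraph, a: str, b: str,
                      relations: Iterable[str]) -> set[str]:
    ca = ontology.ancestors(a, relations) | {a}
    cb = ontology.ancestors(b, relations) | {b}
    return ca & cb


def resnik_similarity(counts: CorpusCounts, ontology: OntologyGraph, a: str, b: str,
                      relations: Iterable[str] = ("is_a", "part_of")) -> float:
    """IC of the most informative common ancestor (0 if none exists).

    A term counts as its own ancestor here, so ``resnik(A, A) = IC(A)`` and a
    parent–child pair scores the parent's IC.
    """
    a = ontology.resolve(a)
    b = ontology.resolve(b)
    common = _common_ancestors(ontology, a, b, relations)
    ics = [counts.ic[t] for t in common if not math.isnan(counts.ic[t])]
    if not ics:
        return 0.0
    return max(ics)


def lin_similarity(counts: CorpusCounts, ontology: OntologyGraph, a: str, b: str,
                   relations: Iterable[str] = ("is_a", "part_of")) -> float:
    """2·IC(MICA) / (IC(A) + IC(B)); defined as 0 when both ICs are zero."""
    a = ontology.resolve(a)
    b = ontology.resolve(b)
    ic_a, ic_b = counts.ic[a], counts.ic[b]
    if math.isnan(ic_a) or math.isnan(ic_b):
        raise ValueError(f"IC undefined for {a if math.isnan(ic_a) else b}")
    if ic_a + ic_b == 0.0:
        warnings.warn(f"both {a} and {b} have zero IC; Lin similarity defined as 0",
                      stacklevel=2)
        return 0.0
    return 2.0 * resnik_similarity(counts, ontology, a, b, relations) / (ic_a + ic_b)


@dataclass
class ChildrenICReport:
    """Grouped children-count vs average-IC table and its correlations."""

    namespace: str
    table: pd.DataFrame  # columns: nc, mean_ic, log_mean_ic, n_terms
    spearman: float
    pearson: float
    pearson_defined: bool
    n_groups_dropped_large: int
    n_groups_dropped_nonpositive: int


def children_ic_correlation(ontology: OntologyGraph, counts: CorpusCounts,
                            max_children: int = 100,
                            relations: Iterable[str] = ("is_a", "part_of"),
                            ) -> dict[str, ChildrenICReport]:
    """Correlate the log of group-average IC with the number of children.

    Terms are grouped by their direct-children count ``nc``; groups with
    ``nc > max_children`` (extreme, near-zero-IC points) are dropped, as are
    groups whose average IC is not positive (their log is undefined).
    Requires at least 3 surviving groups per namespace.
    """
    reports: dict[str, ChildrenICReport] = {}
    for ns in sorted(set(ontology.namespaces.values())):
        rows = []
        for term in ontology.graph.nodes:
            if ontology.namespaces[term] != ns:
                continue
            icv = counts.ic[term]
            if math.isnan(icv):
                continue
            rows.append((children_count(ontology, term, relations), icv))
        if not rows:
            continue
        df = pd.DataFrame(rows, columns=["nc", "ic"])
        grouped = df.groupby("nc").agg(mean_ic=("ic", "mean"), n_terms=("ic", "size"))
        grouped = grouped.reset_index()
        n_large = int((grouped["nc"] > max_children).sum())
        grouped = grouped[grouped["nc"] <= max_children]
        n_nonpos = int((grouped["mean_ic"] <= 0).sum())
        grouped = grouped[grouped["mean_ic"] > 0].copy()
        if len(grouped) < 3:
            raise ValueError(
                f"namespace {ns}: only {len(grouped)} usable nc groups; "
                "correlation undefined (need ≥ 3)")
        grouped["log_mean_ic"] = np.log(grouped["mean_ic"].to_numpy())

        x = grouped["nc"].to_numpy(dtype=float)
        y = grouped["log_mean_ic"].to_numpy()
        spearman = float(stats.spearmanr(x, y).statistic)
        if np.ptp(y) == 0.0 or np.ptp(x) == 0.0:
            pearson, pearson_defined = 0.0, False
        else:
            pearson, pearson_defined = float(stats.pearsonr(x, y).statistic), True

        reports[ns] = ChildrenICReport(
            namespace=ns,
            table=grouped[["nc", "mean_ic", "log_mean_ic", "n_terms"]],
            spearman=spearman,
            pearson=pearson,
            pearson_defined=pearson_defined,
            n_groups_dropped_large=n_large,
            n_groups_dropped_nonpositive=n_nonpos,
        )
    return reports


def ic_table(ontology: OntologyGraph, counts: CorpusCounts) -> pd.DataFrame:
    """Per-term TSV-ready table: term, namespace, raw, propagated, IC."""
    rows = [
        (t, ontology.namespaces[t], counts.raw_counts.get(t, 0),
         counts.propagated_counts[t], counts.ic[t])
        for t in sorted(ontology.graph.nodes)
    ]
    return pd.DataFrame(rows, columns=["term", "namespace", "raw_count",
                                       "propagated_count", "ic"])
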