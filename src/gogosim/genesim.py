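"""Gene-level functional similarity from term-level similarities.

A gene annotated with terms {go_1 … go_m} is compared to another gene by
mixing the m×n pairwise term similarities.  Five mixing strategies are
supported; writing row/column maxima ("best matches") as M_i = max_j S_ij
and N_j = max_i S_ij:

* ``Avg`` — grand mean of all m×n pairwise similarities
* ``Max`` — grand maximum
* ``ABM`` — pooled best-match average, (Σ_i M_i + Σ_j N_j) / (m + n); the default
* ``BMA`` — mean of the two directional best-match averages
* ``BMM`` — maximum of the two directional best-match averages

All five are symmetric and, for single-term genes, reduce to the single term
similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .ontology import AnnotationSet, OntologyGraph
from .semsim import SemSimConfig, TermSimilarityProvider

STRATEGIES = ("Avg", "Max", "ABM", "BMA", "BMM")

TermSim = Callable[[str, str], float]


@dataclass
class SimilarityMatrix:
    """Symmetric term×term or gene×gene similarity matrix in [0, 1]."""

    labels: tuple[str, ...]
    values: np.ndarray
    namespace: str = ""
    strategy: str | None = None
    excluded: tuple[str, ...] = ()  # genes dropped for lack of terms in the namespace

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} labels")
        if n and not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix is not symmetric within 1e-12")
        if n and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise ValueError("similarity values fall outside [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def _normalize_strategy(strategy: str) -> str:
    for s in STRATEGIES:
        if s.lower() == strategy.lower():
            return s
    raise ValueError(f"unknown mixing strategy {strategy!r}; choose from {STRATEGIES}")


def term_to_gene_similarity(go: str, gene_terms: Sequence[str], termsim: TermSim) -> float:
    """Best match of a single term against a gene's term list."""
    if not gene_terms:
        raise ValueError("gene has no terms in this namespace")
    return max(termsim(go, t) for t in gene_terms)


def gene_similarity(g1_terms: Sequence[str], g2_terms: Sequence[str],
                    strategy: str = "ABM", termsim: TermSim | None = None) -> float:
    """Mix pairwise term similarities into one gene-pair functional similarity."""
    if termsim is None:
        raise ValueError("a term-similarity provider is required")
    if not g1_terms or not g2_terms:
        raise ValueError("both genes must have at least one term")
    strategy = _normalize_strategy(strategy)
    m, n = len(g1_terms), len(g2_terms)
    sims = np.empty((m, n))
    for i, a in enumerate(g1_terms):
        for j, b in enumerate(g2_terms):
            sims[i, j] = termsim(a, b)

    row_best = sims.max(axis=1)  # best match of each G1 term in G2
    col_best = sims.max(axis=0)  # best match of each G2 term in G1
    if strategy == "Avg":
        return float(sims.mean())
    if strategy == "Max":
        return float(sims.max())
    if strategy == "ABM":
        return float((row_best.sum() + col_best.sum()) / (m + n))
    if strategy == "BMA":
        return float(0.5 * (row_best.mean() + col_best.mean()))
    return float(max(row_best.mean(), col_best.mean()))  # BMM


def pairwise_gene_matrix(ontology: OntologyGraph, annotations: AnnotationSet,
                         gene_list: Iterable[str], namespace: str = "BPO",
                         strategy: str = "ABM",
                         config: SemSimConfig | None = None,
                         provider: TermSimilarityProvider | None = None,
                         ) -> SimilarityMatrix:
    """Gene×gene functional-similarity matrix within one namespace.

    Genes with no annotated terms in the namespace are excluded and reported
    via ``SimilarityMatrix.excluded``; the diagonal is set to 1.
    """
    strategy = _normalize_strategy(strategy)
    gene_list = list(gene_list)
    if not gene_list:
        raise ValueError("gene list is empty")
    if provider is None:
        provider = TermSimilarityProvider(ontology, config or SemSimConfig())

    kept: list[str] = []
    terms: dict[str, list[str]] = {}
    excluded: list[str] = []
    for gene in gene_list:
        ts = annotations.terms_for(gene, namespace)
        if ts:
            kept.append(gene)
            terms[gene] = ts
        else:
            excluded.append(gene)
    if not kept:
        raise ValueError(f"no input gene has terms in namespace {namespace}")

    n = len(kept)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            v = gene_similarity(terms[kept[i]], terms[kept[j]], strategy, provider)
            values[i, j] = values[j, i] = v
    return SimilarityMatrix(
        labels=tuple(kept), values=values, namespace=namespace,
        strategy=strategy, excluded=tuple(excluded),
    )
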