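"""Evaluating gene clusterings against reference pathways with per-gene MCC,
plus the noise-gene injection and pair-sampling procedures used in
comparative benchmarks.

A predicted partition is scored against reference clusters gene by gene:
for gene g, every other gene g′ is a true positive if g and g′ share both a
reference cluster and a predicted cluster, a true negative if they share
neither, and so on; the per-gene Matthews correlation coefficient condenses
those counts, cluster scores average their member genes, and the overall
score averages the clusters.  Noise genes drawn from outside the pathway are
appended as one extra reference cluster before scoring.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment
from .ontology import AnnotationSet, OntologyGraph
from .semsim import SemSimConfig, TermSimilarityProvider

NOISE_CLUSTER = "__noise__"


@dataclass
class ReferencePathway:
    """Reference clusters (e.g. a pathway's enzyme groups) and optional EC numbers."""

    labels: dict[str, str]  # gene -> reference cluster label
    ec: dict[str, str] = field(default_factory=dict)  # gene -> EC number

    def __post_init__(self) -> None:
        for gene, number in self.ec.items():
            if len(number.split(".")) < 2:
                raise ValueError(f"EC number {number!r} of {gene} has fewer than 2 levels")

    @property
    def genes(self) -> set[str]:
        return set(self.labels)

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gene, label in self.labels.items():
            out.setdefault(label, []).append(gene)
        return {k: sorted(v) for k, v in out.items()}


@dataclass
class MCCReport:
    """Per-gene confusion counts and MCC, per-cluster and overall averages."""

    per_gene: dict[str, tuple[int, int, int, int, float]]  # (TP, TN, FP, FN, MCC)
    per_cluster: dict[str, float]
    overall: float

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(g, *v) for g, v in sorted(self.per_gene.items())]
        return pd.DataFrame(rows, columns=["gene", "tp", "tn", "fp", "fn", "mcc"])


def mcc_score(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient of a 2×2 confusion matrix.

    (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)); 0 whenever any factor
    of the denominator is zero (the standard convention).
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def evaluate_clustering(predicted: ClusterAssignment, reference: ReferencePathway,
                        noise_genes: Iterable[str] = ()) -> MCCReport:
    """Score a predicted partition against reference clusters gene by gene.

    ``noise_genes`` are appended to the reference as one extra cluster of
    outsiders before counting.  Every evaluated gene must appear in the
    predicted assignment.
    """
    noise = set(noise_genes)
    overlap = noise & reference.genes
    if overlap:
        raise ValueError(f"noise genes overlap the reference: {sorted(overlap)}")
    truth = dict(reference.labels)
    for g in noise:
        truth[g] = NOISE_CLUSTER

    missing = set(truth) - set(predicted.labels)
    if missing:
        raise ValueError(f"genes missing from the predicted assignment: {sorted(missing)}")

    genes = sorted(truth)
    per_gene: dict[str, tuple[int, int, int, int, float]] = {}
    for g in genes:
        tp = tn = fp = fn = 0
        for other in genes:
            if other == g:
                continue
            same_ref = truth[g] == truth[other]
            same_pred = predicted.labels[g] == predicted.labels[other]
            if same_ref and same_pred:
                tp += 1
            elif not same_ref and not same_pred:
                tn += 1
            elif not same_ref and same_pred:
                fp += 1
            else:
                fn += 1
        per_gene[g] = (tp, tn, fp, fn, mcc_score(tp, tn, fp, fn))

    per_cluster: dict[str, float] = {}
    for label, members in itertools.groupby(sorted(genes, key=lambda g: truth[g]),
                                            key=lambda g: truth[g]):
        ms = list(members)
        per_cluster[label] = float(np.mean([per_gene[m][4] for m in ms]))
    overall = float(np.mean(list(per_cluster.values())))
    return MCCReport(per_gene=per_gene, per_cluster=per_cluster, overall=overall)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def inject_noise_genes(reference: ReferencePathway, pool: Iterable[str] | AnnotationSet,
                       fraction: float = 0.5, mode: str = "random",
                       ec_map: Mapping[str, str] | None = None,
                       seed: int = 0) -> set[str]:
    """Select outsider genes to add to a pathway before clustering.

    ``random`` mode draws ``round_half_up(fraction × pathway size)`` genes
    uniformly without replacement from the pool (pathway genes are excluded
    from the pool first).  ``ec_matched`` mode instead draws, per reference
    cluster, outsiders whose first two EC levels match some member of that
    cluster; the quota is split across clusters proportionally to cluster
    size with the remainder going to the largest cluster.
    """
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    if mode not in ("random", "ec_matched"):
        raise ValueError(f"unknown noise mode {mode!r}")
    pool_genes = sorted(set(pool.genes if isinstance(pool, AnnotationSet) else pool)
                        - reference.genes)
    n_ref = len(reference.genes)
    k = _round_half_up(fraction * n_ref)
    rng = np.random.default_rng(seed)

    if mode == "random":
        if len(pool_genes) < k:
            raise ValueError(f"pool has {len(pool_genes)} eligible genes; "
                             f"{k} required (short by {k - len(pool_genes)})")
        picked = rng.choice(pool_genes, size=k, replace=False)
        return set(picked.tolist())

    # ec_matched
    if ec_map is None:
        raise ValueError("ec_matched mode requires an EC map for the pool genes")
    if not reference.ec:
        raise ValueError("ec_matched mode requires EC numbers on the reference genes")

    def top2(number: str) -> tuple[str, str]:
        parts = number.split(".")
        return parts[0], parts[1]

    clusters = reference.clusters()
    sizes = {label: len(members) for label, members in clusters.items()}
    quotas = {label: int(math.floor(fraction * size + 1e-9)) for label, size in sizes.items()}
    shortfall = k - sum(quotas.values())
    if shortfall > 0:
        largest = max(sizes, key=lambda L: (sizes[L], L))
        quotas[largest] += shortfall

    chosen: set[str] = set()
    for label in sorted(clusters):
        quota = quotas[label]
        if quota == 0:
            continue
        member_keys = set()
        for g in clusters[label]:
            if g in reference.ec:
                member_keys.add(top2(reference.ec[g]))
        if not member_keys:
            raise ValueError(f"cluster {label!r} has no EC numbers; cannot EC-match")
        eligible = [g for g in pool_genes
                    if g not in chosen and g in ec_map and top2(ec_map[g]) in member_keys]
        if len(eligible) < quota:
            raise ValueError(
                f"cluster {label!r}: only {len(eligible)} EC-matched pool genes; "
                f"{quota} required (short by {quota - len(eligible)})")
        picked = rng.choice(eligible, size=quota, replace=False)
        chosen.update(picked.tolist())
    return chosen


# -- pair sampling for method comparisons -------------------------------------


def sample_term_pairs(ontology: OntologyGraph, n: int, min_wang_sim: float | None = None,
                      config: SemSimConfig | None = None, seed: int = 0,
                      namespace: str = "BPO", max_attempts: int | None = None,
                      ) -> list[tuple[str, str]]:
    """Sample distinct unordered term pairs within one namespace.

    With ``min_wang_sim`` set, pairs are rejection-sampled until ``n`` pass
    the constant-weight (Wang) similarity threshold — random pairs mostly
    have very low similarity, so thresholding keeps the comparison on pairs
    the methods actually disagree about.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    terms = sorted(t for t in ontology.graph.nodes if ontology.namespaces[t] == namespace)
    if len(terms) < 2:
        raise ValueError(f"namespace {namespace} has fewer than 2 terms")
    rng = np.random.default_rng(seed)
    provider = None
    if min_wang_sim is not None:
        wang_cfg = config if (config is not None and config.method == "wang") \
            else SemSimConfig.wang()
        provider = TermSimilarityProvider(ontology, wang_cfg)
    budget = max_attempts if max_attempts is not None else max(10_000, 2_000 * n)

    chosen: set[tuple[str, str]] = set()
    attempts = 0
    accepted = 0
    while len(chosen) < n:
        if attempts >= budget:
            rate = accepted / attempts if attempts else 0.0
            raise RuntimeError(
                f"could not collect {n} pairs within {budget} attempts "
                f"(acceptance rate {rate:.4f})")
        attempts += 1
        i, j = rng.choice(len(terms), size=2, replace=False)
        pair = (terms[min(i, j)], terms[max(i, j)])
        if pair in chosen:
            continue
        if provider is not None and provider(*pair) < min_wang_sim:
            continue
        accepted += 1
        chosen.add(pair)
    return sorted(chosen)


def term_depths(ontology: OntologyGraph, namespace: str,
                relations: Iterable[str] = ("is_a", "part_of")) -> dict[str, int]:
    """Minimum edge count from the namespace root (root = depth 0)."""
    roots = ontology.roots(namespace)
    depths: dict[str, int] = {r: 0 for r in roots}
    frontier = sorted(roots)
    while frontier:
        nxt = []
        for node in frontier:
            for child in sorted(ontology.children(node, relations)):
                if ontology.namespaces[child] != namespace:
                    continue
                if child not in depths:
                    depths[child] = depths[node] + 1
                    nxt.append(child)
        frontier = nxt
    return depths


def sample_sibling_pairs(ontology: OntologyGraph, depth: int, n: int, seed: int = 0,
                         namespace: str = "BPO",
                         relations: Iterable[str] = ("is_a", "part_of"),
                         ) -> list[tuple[str, str]]:
    """Sample pairs of sibling terms (sharing a parent) both at a given depth."""
    if depth < 1:
        raise ValueError("depth must be ≥ 1")
    depths = term_depths(ontology, namespace, relations)
    eligible: set[tuple[str, str]] = set()
    for parent in sorted(depths):
        kids = sorted(c for c in ontology.children(parent, relations)
                      if depths.get(c) == depth)
        for a, b in itertools.combinations(kids, 2):
            eligible.add((a, b))
    if len(eligible) < n:
        raise ValueError(f"only {len(eligible)} sibling pairs at depth {depth}; {n} requested")
    ordered = sorted(eligible)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ordered), size=n, replace=False)
    return [ordered[i] for i in sorted(idx.tolist())]


def method_correlation_matrix(pairs: Sequence[tuple[str, str]],
                              methods: Mapping[str, Callable[[str, str], float]],
                              ) -> tuple[pd.DataFrame, set[str]]:
    """Pearson correlations between similarity methods over a shared pair list.

    Returns the symmetric unit-diagonal matrix plus the set of methods whose
    outputs had zero variance (their off-diagonal correlations are NaN).
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    if len(methods) < 2:
        raise ValueError("need at least 2 methods")
    names = list(methods)
    vectors = {name: np.array([methods[name](a, b) for a, b in pairs]) for name in names}
    flagged = {name for name, v in vectors.items() if np.ptp(v) == 0.0}
    k = len(names)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            if names[i] in flagged or names[j] in flagged:
                out[i, j] = out[j, i] = np.nan
            else:
                out[i, j] = out[j, i] = float(np.corrcoef(vectors[names[i]],
                                                          vectors[names[j]])[0, 1])
    return pd.DataFrame(out, index=names, columns=names), flagged
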