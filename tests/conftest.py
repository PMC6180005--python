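"""Shared fixtures: tiny hand-written ontologies and independent oracles.

The oracles deliberately avoid the library's dynamic-programming path: S-values
are recomputed by exhaustive enumeration of ascending paths, so the tests can
confirm the propagation machinery rather than restate it.
"""

from __future__ import annotations

import pytest

from gogosim import (
    FixtureSpec,
    OntologyGraph,
    SemSimConfig,
    edge_weight,
    generate_ontology,
    parse_obo,
)

DIAMOND_OBO = """\
format-version: 1.2
data-version: test-fixture

[Term]
id: GO:0000001
name: root
namespace: molecular_function

[Term]
id: GO:0000002
name: left
namespace: molecular_function
is_a: GO:0000001

[Term]
id: GO:0000003
name: right
namespace: molecular_function
relationship: part_of GO:0000001

[Term]
id: GO:0000004
name: bottom
namespace: molecular_function
alt_id: GO:0000044
is_a: GO:0000002
is_a: GO:0000003

[Term]
id: GO:0000005
name: extra child of root
namespace: molecular_function
is_a: GO:0000001

[Term]
id: GO:0000099
name: retired
namespace: molecular_function
is_obsolete: true
"""

CHAIN_OBO = """\
format-version: 1.2

[Term]
id: GO:0000010
name: chain root
namespace: biological_process

[Term]
id: GO:0000011
name: chain mid
namespace: biological_process
is_a: GO:0000010

[Term]
id: GO:0000012
name: chain leaf
namespace: biological_process
is_a: GO:0000011
"""


@pytest.fixture
def diamond() -> OntologyGraph:
    return parse_obo(DIAMOND_OBO)


@pytest.fixture
def chain() -> OntologyGraph:
    return parse_obo(CHAIN_OBO)


@pytest.fixture
def random_dag_factory():
    """Seeded small random DAGs for property checks."""

    def make(seed: int, n_terms: int = 20, **kw) -> OntologyGraph:
        spec = FixtureSpec(n_terms=n_terms, max_depth=kw.pop("max_depth", 5),
                           extra_parent_rate=kw.pop("extra_parent_rate", 0.3),
                           seed=seed, **kw)
        return generate_ontology(spec)

    return make


# -- independent oracles ------------------------------------------------------


def brute_force_s_values(ontology: OntologyGraph, target: str,
                         config: SemSimConfig) -> dict[str, float]:
    """S-values by exhaustive path enumeration: max product over all paths."""
    ns = ontology.namespaces[ontology.resolve(target)]
    products: dict[str, list[float]] = {ontology.resolve(target): [1.0]}

    def dfs(node: str, prod: float) -> None:
        for parent, rel in ontology.parents(node, config.relations):
            if ontology.namespaces[parent] != ns:
                continue
            w = edge_weight(ontology, parent, rel, config)
            products.setdefault(parent, []).append(prod * w)
            dfs(parent, prod * w)

    dfs(ontology.resolve(target), 1.0)
    return {t: max(vals) for t, vals in products.items()}


def brute_force_term_similarity(ontology: OntologyGraph, a: str, b: str,
                                config: SemSimConfig) -> float:
    """Pooled shared-ancestor S-values over summed semantic values, computed
    entirely from the path-enumeration oracle."""
    sa = brute_force_s_values(ontology, a, config)
    sb = brute_force_s_values(ontology, b, config)
    common = set(sa) & set(sb)
    if not common:
        return 0.0
    return sum(sa[t] + sb[t] for t in common) / (sum(sa.values()) + sum(sb.values()))


def brute_force_pair_counts(truth: dict[str, str], predicted: dict[str, int],
                            gene: str) -> tuple[int, int, int, int]:
    """Confusion counts for one gene by explicit enumeration of all other genes."""
    tp = tn = fp = fn = 0
    for other in truth:
        if other == gene:
            continue
        same_ref = truth[gene] == truth[other]
        same_pred = predicted[gene] == predicted[other]
        tp += same_ref and same_pred
        tn += (not same_ref) and (not same_pred)
        fp += (not same_ref) and same_pred
        fn += same_ref and (not same_pred)
    return tp, tn, fp, fn
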