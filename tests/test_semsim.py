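"""S-value propagation, edge weights and term similarity.

The dynamic-programming S-values are checked against exhaustive enumeration
of ascending paths (max product of edge weights), and the printed-arithmetic
examples are asserted directly.
"""

import math

import pytest

from gogosim import (
    ConfigError,
    FixtureSpec,
    SemSimConfig,
    TermSimilarityProvider,
    build_ancestor_graph,
    children_count,
    edge_weight,
    generate_ontology,
    parse_obo,
    semantic_value,
    term_similarity,
)

from conftest import brute_force_s_values, brute_force_term_similarity


def star_obo(n_children: int, relation: str = "is_a") -> str:
    """A parent under a root with ``n_children`` direct children."""
    rel_line = (lambda p: f"is_a: {p}") if relation == "is_a" else \
        (lambda p: f"relationship: {relation} {p}")
    parts = [
        "format-version: 1.2\n",
        "[Term]\nid: GO:0000001\nname: root\nnamespace: biological_process\n",
        "[Term]\nid: GO:0000002\nname: hub\nnamespace: biological_process\n"
        "is_a: GO:0000001\n",
    ]
    for i in range(n_children):
        parts.append(
            f"[Term]\nid: GO:{100 + i:07d}\nname: kid {i}\n"
            f"namespace: biological_process\n{rel_line('GO:0000002')}\n")
    return "\n".join(parts)


class TestConfig:
    def test_c_below_minimum_rejected(self):
        with pytest.raises(ConfigError, match="0.67"):
            SemSimConfig(c=0.5)

    def test_unsafe_flag_permits_small_c_but_weight_check_fires(self):
        # with c = 0.5, nc = 1 and d = 0.4 the weight is 1/1.5 + 0.4 > 1
        ont = parse_obo(star_obo(1))
        cfg = SemSimConfig(c=0.5, allow_unsafe_c=True)
        with pytest.raises(ConfigError, match="outside"):
            edge_weight(ont, "GO:0000002", "is_a", cfg)

    def test_weight_bound_holds_for_safe_c_grid(self):
        ont = parse_obo(star_obo(1))
        for c in (0.67, 1.0, 2.0, 3.0):
            for rel_ont, rel in ((ont, "is_a"),):
                w = edge_weight(rel_ont, "GO:0000002", rel, SemSimConfig(c=c))
                assert 0.0 < w <= 1.0

    def test_bad_weight_tables_rejected(self):
        with pytest.raises(ConfigError):
            SemSimConfig(d_weights=(("is_a", 1.2), ("part_of", 0.3), ("regulates", 0.2)))
        with pytest.raises(ConfigError):
            SemSimConfig(method="nope")


class TestChildrenCount:
    def test_leaf_is_zero(self, diamond):
        assert children_count(diamond, "GO:0000004") == 0

    def test_counts_respect_relation_subset(self, diamond):
        # root has is_a children GO:0000002, GO:0000005 and part_of child GO:0000003
        assert children_count(diamond, "GO:0000001", ("is_a",)) == 2
        assert children_count(diamond, "GO:0000001", ("is_a", "part_of")) == 3

    def test_distinct_children_only(self):
        # one child linked by two relations still counts once
        obo = ("format-version: 1.2\n\n"
               "[Term]\nid: GO:0000001\nname: r\nnamespace: biological_process\n\n"
               "[Term]\nid: GO:0000002\nname: k\nnamespace: biological_process\n"
               "is_a: GO:0000001\nrelationship: part_of GO:0000001\n")
        ont = parse_obo(obo)
        assert children_count(ont, "GO:0000001") == 1


class TestEdgeWeight:
    def test_is_a_with_one_child(self):
        ont = parse_obo(star_obo(0))  # hub is the only child of root
        w = edge_weight(ont, "GO:0000001", "is_a", SemSimConfig())
        assert w == pytest.approx(1 / 1.67 + 0.4, abs=1e-12)

    def test_part_of_with_nine_children(self):
        ont = parse_obo(star_obo(9, relation="part_of"))
        w = edge_weight(ont, "GO:0000002", "part_of", SemSimConfig())
        assert w == pytest.approx(1 / 9.67 + 0.3, abs=1e-12)

    def test_wang_mode_uses_constant(self):
        ont = parse_obo(star_obo(9))
        w = edge_weight(ont, "GO:0000002", "is_a", SemSimConfig.wang())
        assert w == 0.8  # independent of the children count


class TestAncestorGraph:
    def test_root_graph_is_singleton(self, chain):
        g = build_ancestor_graph(chain, "GO:0000010")
        assert g.node_set == frozenset({"GO:0000010"})
        assert g.s_values == {"GO:0000010": 1.0}
        assert semantic_value(g) == 1.0

    def test_chain_s_values_are_weight_products(self, chain):
        # GO:0000012 -> GO:0000011 -> GO:0000010, each parent with one child
        g = build_ancestor_graph(chain, "GO:0000012")
        w = 1 / 1.67 + 0.4
        assert g.s_values["GO:0000012"] == 1.0
        assert g.s_values["GO:0000011"] == pytest.approx(w, abs=1e-12)
        assert g.s_values["GO:0000010"] == pytest.approx(w * w, abs=1e-12)
        assert semantic_value(g) == pytest.approx(1 + w + w * w, abs=1e-12)

    def test_diamond_takes_max_path(self, diamond):
        g = build_ancestor_graph(diamond, "GO:0000004")
        oracle = brute_force_s_values(diamond, "GO:0000004", SemSimConfig())
        assert set(g.s_values) == set(oracle)
        for t, v in oracle.items():
            assert g.s_values[t] == pytest.approx(v, abs=1e-12)

    def test_proper_ancestor_s_values_strictly_inside_unit_interval(self, diamond):
        g = build_ancestor_graph(diamond, "GO:0000004")
        for t, v in g.s_values.items():
            if t == "GO:0000004":
                assert v == 1.0
            else:
                assert 0.0 < v < 1.0

    def test_every_nonroot_node_has_child_in_closure(self, random_dag_factory):
        ont = random_dag_factory(seed=11, n_terms=25)
        term = sorted(ont.terms)[-1]
        g = build_ancestor_graph(ont, term)
        children_inside = {p: False for p in g.node_set if p != g.target}
        for child, parent, _ in g.edge_set:
            if parent in children_inside:
                children_inside[parent] = True
        assert all(children_inside.values())


class TestTermSimilarity:
    def test_identity_is_one(self, diamond):
        for t in diamond.terms:
            assert term_similarity(diamond, t, t) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_and_range(self, random_dag_factory):
        ont = random_dag_factory(seed=4, n_terms=18)
        terms = sorted(ont.terms)
        for a in terms[::3]:
            for b in terms[1::4]:
                s_ab = term_similarity(ont, a, b)
                s_ba = term_similarity(ont, b, a)
                assert s_ab == s_ba
                assert 0.0 < s_ab <= 1.0  # single-root namespace: never disjoint

    def test_ancestor_disjoint_pair_scores_zero(self):
        two_roots = ("format-version: 1.2\n\n"
                     "[Term]\nid: GO:0000001\nname: r1\nnamespace: biological_process\n\n"
                     "[Term]\nid: GO:0000002\nname: r2\nnamespace: biological_process\n")
        ont = parse_obo(two_roots)
        assert term_similarity(ont, "GO:0000001", "GO:0000002") == 0.0

    def test_cross_namespace_requires_flag(self, diamond, chain):
        obo = ("format-version: 1.2\n\n"
               "[Term]\nid: GO:0000001\nname: p\nnamespace: biological_process\n\n"
               "[Term]\nid: GO:0000002\nname: f\nnamespace: molecular_function\n")
        ont = parse_obo(obo)
        with pytest.raises(ValueError, match="namespace"):
            term_similarity(ont, "GO:0000001", "GO:0000002")

    def test_leaves_sharing_only_root_match_oracle(self):
        obo = ("format-version: 1.2\n\n"
               "[Term]\nid: GO:0000001\nname: r\nnamespace: biological_process\n\n"
               "[Term]\nid: GO:0000002\nname: a\nnamespace: biological_process\n"
               "is_a: GO:0000001\n\n"
               "[Term]\nid: GO:0000003\nname: b\nnamespace: biological_process\n"
               "relationship: part_of GO:0000001\n\n"
               "[Term]\nid: GO:0000004\nname: la\nnamespace: biological_process\n"
               "is_a: GO:0000002\n\n"
               "[Term]\nid: GO:0000005\nname: lb\nnamespace: biological_process\n"
               "is_a: GO:0000003\n")
        ont = parse_obo(obo)
        cfg = SemSimConfig()
        got = term_similarity(ont, "GO:0000004", "GO:0000005", cfg)
        want = brute_force_term_similarity(ont, "GO:0000004", "GO:0000005", cfg)
        assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("method", ["gogo", "wang"])
    def test_dp_matches_path_enumeration_on_random_dags(self, random_dag_factory, method):
        cfg = SemSimConfig() if method == "gogo" else SemSimConfig.wang()
        for seed in range(30):
            ont = random_dag_factory(seed=100 + seed, n_terms=5 + seed % 26)
            for term in sorted(ont.terms):
                g = build_ancestor_graph(ont, term, cfg)
                oracle = brute_force_s_values(ont, term, cfg)
                assert set(g.s_values) == set(oracle)
                for t, v in oracle.items():
                    assert g.s_values[t] == pytest.approx(v, abs=1e-12)

    def test_provider_cache_matches_fresh_computation(self, random_dag_factory):
        ont = random_dag_factory(seed=7, n_terms=15)
        provider = TermSimilarityProvider(ont)
        terms = sorted(ont.terms)
        for a, b in zip(terms, terms[2:]):
            assert provider(a, b) == term_similarity(ont, a, b)
            assert provider(a, b) == provider(b, a)  # served from cache


class TestChildrenCountMonotonicity:
    """Attaching extra children to the bottleneck ancestor lowers similarity:
    a crowded ancestor passes less semantic contribution to each child."""

    @staticmethod
    def _two_leaf_obo(extra_children: int) -> str:
        parts = [
            "format-version: 1.2\n",
            "[Term]\nid: GO:0000001\nname: root\nnamespace: biological_process\n",
            "[Term]\nid: GO:0000002\nname: mid\nnamespace: biological_process\n"
            "is_a: GO:0000001\n",
            "[Term]\nid: GO:0000003\nname: leaf a\nnamespace: biological_process\n"
            "is_a: GO:0000002\n",
            "[Term]\nid: GO:0000004\nname: leaf b\nnamespace: biological_process\n"
            "is_a: GO:0000002\n",
        ]
        for i in range(extra_children):
            parts.append(
                f"[Term]\nid: GO:{200 + i:07d}\nname: sib {i}\n"
                f"namespace: biological_process\nis_a: GO:0000002\n")
        return "\n".join(parts)

    def test_similarity_strictly_decreases_with_crowding(self):
        sims = []
        for extra in (0, 3, 10, 28):
            ont = parse_obo(self._two_leaf_obo(extra))
            sims.append(term_similarity(ont, "GO:0000003", "GO:0000004"))
        assert all(a > b for a, b in zip(sims, sims[1:]))

    def test_crowding_elsewhere_cannot_raise_similarity(self):
        # extra children under the *root* only touch the root's own weight
        base = parse_obo(self._two_leaf_obo(0))
        crowded_root = self._two_leaf_obo(0) + (
            "\n[Term]\nid: GO:0000300\nname: unrelated\n"
            "namespace: biological_process\nis_a: GO:0000001\n")
        crowded = parse_obo(crowded_root)
        assert term_similarity(crowded, "GO:0000003", "GO:0000004") <= \
            term_similarity(base, "GO:0000003", "GO:0000004")
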