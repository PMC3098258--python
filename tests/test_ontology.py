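"""Ontology parsing, levels, descendant counts and granularity weights."""

import numpy as np
import networkx as nx
import pytest

from gpnet.ontology import (
    OntologyDAG,
    OntologyError,
    OntologyTerm,
    granularity_weight,
    level_usage_histogram,
    parse_obo_str,
)
from gpnet.synthetic_data import _random_dag

from conftest import annset


class TestParsing:
    def test_minimal_chain(self):
        dag = parse_obo_str(
            "format-version: 1.2\nontology: t\n\n[Term]\nid: R\nname: r\n\n"
            "[Term]\nid: A\nname: a\nis_a: R\n\n[Term]\nid: B\nname: b\nis_a: A\n"
        )
        assert set(dag.terms) == {"R", "A", "B"}
        assert dag.terms["B"].parents == {"A"}
        assert dag.root == "R"

    def test_multi_parent_stanza(self, tiny_dag):
        assert tiny_dag.terms["T:d1"].parents == {"T:a1", "T:a2"}

    def test_obsolete_terms_excluded(self):
        dag = parse_obo_str(
            "format-version: 1.2\nontology: t\n\n[Term]\nid: R\nname: r\n\n"
            "[Term]\nid: A\nname: a\nis_a: R\n\n"
            "[Term]\nid: X\nname: gone\nis_a: R\nis_obsolete: true\n"
        )
        assert set(dag.terms) == {"R", "A"}

    def test_missing_root_is_structural_error(self):
        with pytest.raises(OntologyError, match="root"):
            OntologyDAG.from_terms(
                [
                    OntologyTerm("R1", "r1"),
                    OntologyTerm("R2", "r2"),
                    OntologyTerm("A", "a", frozenset({"R1"})),
                ]
            )

    def test_cycle_detected(self):
        with pytest.raises(OntologyError, match="cycle"):
            OntologyDAG.from_terms(
                [
                    OntologyTerm("R", "r"),
                    OntologyTerm("A", "a", frozenset({"R", "B"})),
                    OntologyTerm("B", "b", frozenset({"A"})),
                ]
            )


class TestLevels:
    def test_chain_levels(self, tiny_dag):
        assert tiny_dag.level["T:R"] == 0
        assert tiny_dag.level["T:A"] == 1
        assert tiny_dag.level["T:a3"] == 3

    def test_diamond_shortest_path(self, tiny_dag):
        # d1 reaches the root through both a1 and a2 (each at level 2)
        assert tiny_dag.level["T:d1"] == 3

    def test_asymmetric_diamond_takes_shorter_path(self):
        dag = parse_obo_str(
            "format-version: 1.2\nontology: t\n\n[Term]\nid: R\nname: r\n\n"
            "[Term]\nid: A\nname: a\nis_a: R\n\n[Term]\nid: B\nname: b\nis_a: R\n\n"
            "[Term]\nid: C\nname: c\nis_a: B\n\n"
            "[Term]\nid: X\nname: x\nis_a: A\nis_a: C\n"
        )
        assert dag.level["X"] == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_levels_equal_bfs_distance_on_random_dag(self, seed):
        rng = np.random.default_rng(seed)
        obo, _, _ = _random_dag(rng, depth=5, branching=1.7, n_level1=4,
                                multi_parent_rate=0.15, prefix="RD")
        dag = parse_obo_str(obo)
        g = nx.DiGraph()
        for t in dag.terms.values():
            for p in t.parents:
                g.add_edge(p, t.term_id)
        oracle = nx.single_source_shortest_path_length(g, dag.root)
        assert dag.level == oracle


class TestAnnotatedDescendants:
    def test_leaf_has_none(self, tiny_dag):
        ann = annset(("g1", "T:a1"))
        assert tiny_dag.annotated_descendants(ann, "T:a1") == set()

    def test_root_counts_all_annotated(self, tiny_dag):
        ann = annset(("g", "T:a1"), ("g", "T:a3"), ("h", "T:b1"),
                     ("h", "T:d1"), ("i", "T:a2"))
        assert tiny_dag.annotated_descendants(ann, "T:R") == {
            "T:a1", "T:a3", "T:b1", "T:d1", "T:a2"
        }

    def test_multi_parent_descendant_counted_once(self, tiny_dag):
        ann = annset(("g", "T:d1"))
        # d1 is below A through both a1 and a2 but appears once
        assert tiny_dag.annotated_descendants(ann, "T:A") == {"T:d1"}

    def test_unknown_term_lookup_error(self, tiny_dag):
        with pytest.raises(OntologyError, match="unknown"):
            tiny_dag.annotated_descendants(annset(("g", "T:a1")), "T:none")

    @pytest.mark.parametrize("seed", [3, 4])
    def test_n_j_monotone_towards_root(self, seed):
        rng = np.random.default_rng(seed)
        obo, _, _ = _random_dag(rng, depth=5, branching=1.7, n_level1=4,
                                multi_parent_rate=0.1, prefix="RD")
        dag = parse_obo_str(obo)
        terms = sorted(dag.terms)
        annotated = [t for t in terms if rng.random() < 0.3]
        dag.compute_granularity(annotated)
        for t in terms:
            for p in dag.terms[t].parents:
                assert dag.n_annotated_below[p] >= dag.n_annotated_below[t]


class TestGranularity:
    @pytest.mark.parametrize(
        "n,scheme,expected",
        [(0, "inverse", 1.0), (9, "inverse", 0.1), (3, "linear", 4.0),
         (0, "linear", 1.0)],
    )
    def test_closed_forms(self, n, scheme, expected):
        assert granularity_weight(n, scheme) == pytest.approx(expected)

    def test_negative_count_rejected(self):
        with pytest.raises(OntologyError):
            granularity_weight(-1)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(OntologyError):
            granularity_weight(2, "sqrt")


class TestAncestorsAtLevel:
    def test_single_lineage_self(self, tiny_dag):
        assert tiny_dag.ancestors_at_level("T:a3", 3) == {"T:a3"}
        assert tiny_dag.ancestors_at_level("T:a3", 1) == {"T:A"}

    def test_diamond_gives_both_ancestors(self, tiny_dag):
        # d1 sits below both a1 and a2, so both level-2 ancestors count
        assert tiny_dag.ancestors_at_level("T:d1", 2) == {"T:a1", "T:a2"}
        assert tiny_dag.ancestors_at_level("T:d1", 3) == {"T:d1"}
        assert tiny_dag.ancestors_at_level("T:d1", 1) == {"T:A"}

    def test_true_multi_ancestor_fanout(self):
        # diamond across two level-1 branches: X is_a A and is_a B
        dag = parse_obo_str(
            "format-version: 1.2\nontology: t\n\n[Term]\nid: R\nname: r\n\n"
            "[Term]\nid: A\nname: a\nis_a: R\n\n[Term]\nid: B\nname: b\nis_a: R\n\n"
            "[Term]\nid: X\nname: x\nis_a: A\nis_a: B\n"
        )
        assert dag.ancestors_at_level("X", 1) == {"A", "B"}

    def test_term_above_level_gives_empty(self, tiny_dag):
        assert tiny_dag.ancestors_at_level("T:A", 3) == set()

    @pytest.mark.parametrize("seed", [5, 6])
    def test_tree_gives_unique_ancestor(self, seed):
        rng = np.random.default_rng(seed)
        obo, _, _ = _random_dag(rng, depth=5, branching=1.7, n_level1=4,
                                multi_parent_rate=0.0, prefix="TR")
        dag = parse_obo_str(obo)
        for t, lv in dag.level.items():
            for L in range(1, lv + 1):
                assert len(dag.ancestors_at_level(t, L)) == 1


class TestLevelHistogram:
    def test_all_one_level(self, tiny_dag):
        ann = annset(*((f"g{i}", "T:a3") for i in range(10)))
        assert level_usage_histogram(ann, tiny_dag) == {3: 10}

    def test_mixed_hand_count(self, tiny_dag):
        ann = annset(("g", "T:A"), ("g", "T:a1"), ("h", "T:a1"),
                     ("h", "T:a3"), ("h", "T:d1"))
        assert level_usage_histogram(ann, tiny_dag) == {1: 1, 2: 2, 3: 2}

    def test_empty(self, tiny_dag):
        assert level_usage_histogram(annset(), tiny_dag) == {}
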