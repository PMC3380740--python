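import numpy as np
import pytest

from hotspot_transreg.go_semantic import (
    AnnotationMap,
    GoDag,
    GoError,
    TermSimilarity,
    gap_score,
    gene_to_reference_terms,
    parse_obo,
    rank_terms_by_gap,
    term_gene_similarity,
    term_geneset_similarity,
)

TOY_OBO = """format-version: 1.2
ontology: toy

[Term]
id: T:0
name: root
namespace: biological_process

[Term]
id: T:1
name: child a
namespace: biological_process
is_a: T:0 ! root

[Term]
id: T:2
name: child b
namespace: biological_process
is_a: T:0 ! root

[Term]
id: T:3
name: gone
namespace: biological_process
is_obsolete: true
"""


class TestParseObo:
    def test_toy_ontology_structure(self, tmp_path):
        p = tmp_path / "toy.obo"
        p.write_text(TOY_OBO)
        dag = parse_obo(p)
        assert len(dag) == 3
        assert dag.graph.number_of_edges() == 2
        assert dag.roots() == ["T:0"]
        assert dag.name("T:1") == "child a"

    def test_obsolete_terms_absent(self, tmp_path):
        p = tmp_path / "toy.obo"
        p.write_text(TOY_OBO)
        assert "T:3" not in parse_obo(p)

    def test_part_of_relationship_kept(self, tmp_path):
        p = tmp_path / "p.obo"
        p.write_text(
            "format-version: 1.2\nontology: toy\n\n"
            "[Term]\nid: T:0\nname: r\nnamespace: bp\n\n"
            "[Term]\nid: T:1\nname: c\nnamespace: bp\nrelationship: part_of T:0 ! r\n"
        )
        dag = parse_obo(p)
        assert dag.graph.edges["T:1", "T:0"]["relation"] == "part_of"


class TestTermSimilarity:
    def test_self_similarity_is_one(self, toy_dag):
        sim = TermSimilarity(toy_dag)
        assert all(sim(t, t) == 1.0 for t in ("R", "A", "B"))

    def test_siblings_hand_computed(self, toy_dag):
        # SV(A)=SV(B)=1.8; common ancestor {R} contributes 0.8 from each side
        sim = TermSimilarity(toy_dag)
        assert sim("A", "B") == pytest.approx(1.6 / 3.6)
        assert sim("A", "B") == sim("B", "A")

    def test_cross_namespace_is_zero(self):
        dag = GoDag.from_edges(
            {"R1": ("r1", "biological_process"), "R2": ("r2", "molecular_function")}, []
        )
        assert TermSimilarity(dag)("R1", "R2") == 0.0

    def test_unknown_term_raises(self, toy_dag):
        with pytest.raises(GoError):
            TermSimilarity(toy_dag)("A", "nope")

    def test_symmetric_and_bounded_on_synthetic_dag(self, small_go_world, rng):
        sim = TermSimilarity(small_go_world.dag)
        terms = small_go_world.dag.terms
        for _ in range(40):
            t1, t2 = rng.choice(terms, size=2)
            v = sim(t1, t2)
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(sim(t2, t1))
            if t1 != t2:
                assert v < 1.0

    def test_parent_child_weight(self, toy_dag):
        # S-values: A contributes 1, R gets 0.8; SV(R)=1
        sim = TermSimilarity(toy_dag)
        assert sim("A", "R") == pytest.approx((0.8 + 1.0) / (1.8 + 1.0))


class TestGeneSimilarity:
    def _ann(self, toy_dag, mapping):
        return AnnotationMap.from_pairs(
            [(g, t) for g, ts in mapping.items() for t in ts], toy_dag
        )

    def test_singleton_annotation_scores_one(self, toy_dag):
        ann = self._ann(toy_dag, {"g": ["A"]})
        assert term_gene_similarity(TermSimilarity(toy_dag), "A", "g", ann) == 1.0

    def test_two_term_average(self, toy_dag):
        ann = self._ann(toy_dag, {"g": ["A", "B"]})
        s = term_gene_similarity(TermSimilarity(toy_dag), "A", "g", ann)
        assert s == pytest.approx((1.0 + 1.6 / 3.6) / 2)

    def test_unannotated_gene_raises_not_zero(self, toy_dag):
        ann = self._ann(toy_dag, {"g": ["A"]})
        with pytest.raises(GoError):
            term_gene_similarity(TermSimilarity(toy_dag), "A", "other", ann)

    def test_geneset_mean_and_exclusion(self, toy_dag):
        ann = self._ann(toy_dag, {"g1": ["A"], "g2": ["A", "B"]})
        sim = TermSimilarity(toy_dag)
        s1 = term_gene_similarity(sim, "A", "g1", ann)
        s2 = term_gene_similarity(sim, "A", "g2", ann)
        # unannotated g3 is dropped from the average, not scored 0
        got = term_geneset_similarity(sim, "A", ["g1", "g2", "g3"], ann)
        assert got == pytest.approx((s1 + s2) / 2)
        assert term_geneset_similarity(sim, "A", ["g1"], ann) == pytest.approx(s1)

    def test_identical_annotations_average_invariance(self, toy_dag):
        ann = self._ann(toy_dag, {f"g{i}": ["A", "B"] for i in range(5)})
        sim = TermSimilarity(toy_dag)
        per_gene = term_gene_similarity(sim, "B", "g0", ann)
        assert term_geneset_similarity(
            sim, "B", [f"g{i}" for i in range(5)], ann
        ) == pytest.approx(per_gene)

    def test_no_annotated_gene_raises(self, toy_dag):
        ann = self._ann(toy_dag, {"g": ["A"]})
        with pytest.raises(GoError):
            term_geneset_similarity(TermSimilarity(toy_dag), "A", ["x", "y"], ann)


class TestGapScore:
    def test_equal_similarity_gives_zero_gap(self, toy_dag):
        ann = AnnotationMap.from_pairs([("g1", "A"), ("g2", "A")], toy_dag)
        sim = TermSimilarity(toy_dag)
        assert gap_score(sim, "A", ["g1"], ["g1", "g2"], ann) == pytest.approx(0.0)

    def test_relative_excess_arithmetic(self, toy_dag):
        # HG={gA} annotated to A; G adds gB annotated to B
        ann = AnnotationMap.from_pairs([("gA", "A"), ("gB", "B")], toy_dag)
        sim = TermSimilarity(toy_dag)
        s_hg = term_geneset_similarity(sim, "A", ["gA"], ann)
        s_g = term_geneset_similarity(sim, "A", ["gA", "gB"], ann)
        assert gap_score(sim, "A", ["gA"], ["gA", "gB"], ann) == pytest.approx(
            (s_hg - s_g) / s_g
        )
        assert gap_score(sim, "A", ["gA"], ["gA", "gB"], ann) > 0

    def test_zero_background_similarity_warns(self):
        dag = GoDag.from_edges(
            {
                "R": ("r", "biological_process"),
                "M": ("m", "molecular_function"),
            },
            [],
        )
        ann = AnnotationMap.from_pairs([("g", "M")], dag)
        sim = TermSimilarity(dag)
        with pytest.warns(UserWarning, match="gap set to 0"):
            assert gap_score(sim, "R", ["g"], ["g"], ann) == 0.0

    def test_gap_never_below_minus_one(self, small_go_world):
        world = small_go_world
        sim = TermSimilarity(world.dag)
        ranked = rank_terms_by_gap(sim, None, world.hg_genes, world.all_genes, world.annotations)
        assert all(g >= -1.0 for _, g in ranked)


class TestRanking:
    def test_single_term(self, toy_dag):
        ann = AnnotationMap.from_pairs([("g", "A")], toy_dag)
        sim = TermSimilarity(toy_dag)
        ranked = rank_terms_by_gap(sim, ["A"], ["g"], ["g"], ann)
        assert [t for t, _ in ranked] == ["A"]

    def test_ties_broken_by_term_id(self, toy_dag):
        ann = AnnotationMap.from_pairs([("g1", "A"), ("g1", "B")], toy_dag)
        sim = TermSimilarity(toy_dag)
        ranked = rank_terms_by_gap(sim, ["B", "A"], ["g1"], ["g1"], ann)
        assert [t for t, _ in ranked] == ["A", "B"]
        assert ranked[0][1] == ranked[1][1] == pytest.approx(0.0)

    def test_marked_subtree_tops_ranking(self, small_go_world):
        """HG genes annotated inside the marked subtree push every marked
        term above every unmarked term."""
        world = small_go_world
        sim = TermSimilarity(world.dag)
        ranked = rank_terms_by_gap(sim, None, world.hg_genes, world.all_genes, world.annotations)
        gaps = dict(ranked)
        marked = {t for t in world.marked_terms if t in gaps}
        assert marked
        worst_marked = min(gaps[t] for t in marked)
        best_unmarked = max(g for t, g in gaps.items() if t not in marked)
        assert worst_marked > best_unmarked

    def test_top_k_truncation(self, small_go_world):
        world = small_go_world
        sim = TermSimilarity(world.dag)
        ranked = rank_terms_by_gap(
            sim, None, world.hg_genes, world.all_genes, world.annotations, top_k=5
        )
        assert len(ranked) == 5


class TestReferenceTerms:
    def test_single_reference_reduces_to_term_gene(self, toy_dag):
        ann = AnnotationMap.from_pairs([("g", "A"), ("g", "B")], toy_dag)
        sim = TermSimilarity(toy_dag)
        assert gene_to_reference_terms(sim, "g", ["A"], ann) == pytest.approx(
            term_gene_similarity(sim, "A", "g", ann)
        )

    def test_mean_over_two_references(self, toy_dag):
        ann = AnnotationMap.from_pairs([("g", "A"), ("g", "B")], toy_dag)
        sim = TermSimilarity(toy_dag)
        expect = (
            term_gene_similarity(sim, "A", "g", ann) + term_gene_similarity(sim, "B", "g", ann)
        ) / 2
        assert gene_to_reference_terms(sim, "g", ["A", "B"], ann) == pytest.approx(expect)

    def test_empty_reference_list_raises(self, toy_dag):
        ann = AnnotationMap.from_pairs([("g", "A")], toy_dag)
        with pytest.raises(GoError):
            gene_to_reference_terms(TermSimilarity(toy_dag), "g", [], ann)


def test_unknown_annotation_terms_dropped_with_warning(toy_dag):
    with pytest.warns(UserWarning, match="dropped"):
        ann = AnnotationMap.from_pairs([("g", "A"), ("g", "NOPE")], toy_dag)
    assert ann.terms_of("g") == {"A"}


def test_cyclic_ontology_rejected():
    import networkx as nx

    g = nx.DiGraph()
    g.add_edge("A", "B", relation="is_a")
    g.add_edge("B", "A", relation="is_a")
    with pytest.raises(GoError, match="cycle"):
        GoDag(g)
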