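"""Fisher test, levels, elim scan, grouping and cluster-specific tests."""

import math

import numpy as np
import pytest

from dynade.enrichment import (
    GOGroup,
    assign_levels,
    cluster_group_enrichment,
    elim_enrichment,
    fisher_enrichment,
    group_enriched_terms,
    pathway_enrichment,
)
from dynade.ontology import AnnotationMap, OntologyDAG
from dynade.simulate import simulate_ontology


def hypergeom_tail_exact(a: int, s: int, universe: int, selected_total: int) -> float:
    """Integer-arithmetic upper tail P(X >= s) for the oracle."""
    denom = math.comb(universe, a)
    num = sum(
        math.comb(selected_total, j) * math.comb(universe - selected_total, a - j)
        for j in range(s, min(a, selected_total) + 1)
    )
    return num / denom


class TestFisher:
    def test_whole_universe_term_p_one(self):
        assert fisher_enrichment(50, 10, 50, 10) == pytest.approx(1.0)

    def test_small_table_hand_enumeration(self):
        # universe 10, selected 5, term of 2, both selected: C(5,2)/C(10,2)
        assert fisher_enrichment(2, 2, 10, 5) == pytest.approx(10 / 45)

    def test_zero_selected_in_term_p_one(self):
        assert fisher_enrichment(7, 0, 100, 10) == 1.0

    def test_bounds_violations_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(5, 6, 100, 10)
        with pytest.raises(ValueError):
            fisher_enrichment(200, 5, 100, 10)

    def test_matches_exact_enumeration_on_sampled_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            universe = int(rng.integers(1, 61))
            selected_total = int(rng.integers(0, universe + 1))
            a = int(rng.integers(0, universe + 1))
            s = int(rng.integers(0, min(a, selected_total) + 1))
            expect = hypergeom_tail_exact(a, s, universe, selected_total)
            got = fisher_enrichment(a, s, universe, selected_total)
            assert got == pytest.approx(expect, rel=1e-10, abs=1e-12)


class TestLevels:
    def test_fully_selected_term_is_level_one(self, toy_dag):
        ann = AnnotationMap.from_pairs([(f"g{i}", "C") for i in range(5)], dag=toy_dag)
        levels = assign_levels(ann, {f"g{i}" for i in range(5)})
        assert levels["C"] == 1

    def test_two_percent_bands(self, toy_dag):
        genes = [f"g{i}" for i in range(100)]
        ann = AnnotationMap.from_pairs([(g, "C") for g in genes], dag=toy_dag)
        assert assign_levels(ann, set(genes[:97]))["C"] == 2  # 97% -> [96,98)
        assert assign_levels(ann, set(genes[:96]))["C"] == 2  # boundary 96%
        assert assign_levels(ann, set())["C"] == 50  # 0%
        assert assign_levels(ann, set(genes))["C"] == 1  # 100%
        assert assign_levels(ann, set(genes[:98]))["C"] == 1  # boundary 98%


class TestElim:
    @pytest.fixture()
    def planted_case(self):
        """Child fully selected; parent enriched only through the child."""
        genes = [f"g{i}" for i in range(100)]
        selected = set(genes[:10])
        dag = OntologyDAG.from_edges([("C", "A"), ("A", "R")])
        pairs = (
            [(g, "C") for g in genes[:5]]
            + [(g, "A") for g in genes[10:15]]
            + [(g, "R") for g in genes]
        )
        ann = AnnotationMap.from_pairs(pairs, dag=dag, propagate=True)
        return dag, ann, selected

    def test_specific_term_enriched_parent_penalized(self, planted_case):
        dag, ann, selected = planted_case
        res = {r.term: r for r in elim_enrichment(dag, ann, selected)}
        assert res["C"].enriched
        assert res["C"].p_value == pytest.approx(
            hypergeom_tail_exact(5, 5, 100, 10), rel=1e-10
        )
        # parent tested after removal of C's genes: 5 annotated, 0 selected
        assert (res["A"].annotated, res["A"].selected) == (5, 0)
        assert res["A"].p_value == 1.0 and not res["A"].enriched

    def test_alpha_zero_equals_per_term_fisher(self, planted_case):
        dag, ann, selected = planted_case
        res = elim_enrichment(dag, ann, selected, alpha=0.0)
        n_universe = len(ann.genes)
        for r in res:
            genes = ann.term_to_genes[r.term]
            expect = fisher_enrichment(
                len(genes), len(genes & selected), n_universe, len(selected)
            )
            assert r.p_value == pytest.approx(expect, rel=1e-12)
            assert not r.enriched

    def test_post_elim_counts_never_exceed_initial(self, planted_case):
        dag, ann, selected = planted_case
        for r in elim_enrichment(dag, ann, selected):
            initial = ann.term_to_genes[r.term]
            assert r.annotated <= len(initial)
            assert r.selected <= len(initial & selected)

    def test_disjoint_terms_unchanged_by_elim(self):
        dag = OntologyDAG.from_edges([("C", "R"), ("D", "R")])
        genes = [f"g{i}" for i in range(60)]
        selected = set(genes[:8])
        pairs = [(g, "C") for g in genes[:5]] + [(g, "D") for g in genes[20:40]] + [
            (g, "R") for g in genes
        ]
        ann = AnnotationMap.from_pairs(pairs, dag=dag, propagate=True)
        res = {r.term: r for r in elim_enrichment(dag, ann, selected)}
        assert res["C"].enriched
        assert (res["D"].annotated, res["D"].selected) == (20, 0)

    def test_empty_selection_nothing_enriched(self, planted_case):
        dag, ann, _ = planted_case
        res = elim_enrichment(dag, ann, set())
        assert all(r.p_value == 1.0 and not r.enriched for r in res)

    def test_planted_ontology_terms_recovered_ancestors_not(self):
        for seed in range(20):
            onto = simulate_ontology(seed=seed)
            res = elim_enrichment(onto.dag, onto.annotations, onto.selected_genes)
            enriched = {r.term for r in res if r.enriched}
            assert set(onto.planted_terms) <= enriched
            ancestors = set().union(*(onto.dag.ancestors(t) for t in onto.planted_terms))
            assert not (ancestors & enriched)


class TestPathways:
    def test_set_equal_to_universe_p_one(self):
        table = pathway_enrichment({"all": set("abcdef")}, set("ab"), set("abcdef"))
        assert table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_planted_fully_selected_set_significant(self):
        universe = {f"g{i}" for i in range(100)}
        selected = {f"g{i}" for i in range(10)}
        table = pathway_enrichment({"hit": {f"g{i}" for i in range(5)}}, selected, universe)
        assert table.loc[0, "p_value"] == pytest.approx(
            hypergeom_tail_exact(5, 5, 100, 10), rel=1e-10
        )
        assert table.loc[0, "enriched"] == 1

    def test_disjoint_set_skipped(self):
        table = pathway_enrichment({"off": {"x", "y"}}, {"a"}, {"a", "b"})
        assert len(table) == 0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            pathway_enrichment({"s": {"a"}}, {"a"}, set())


class TestGrouping:
    def test_ancestor_pair_plus_isolated_term(self, toy_dag):
        groups = group_enriched_terms(toy_dag, {"B", "C", "D"})
        by_label = {g.label: g for g in groups}
        assert set(by_label) == {"B", "D"}
        assert by_label["B"].members == ["B", "C"]
        assert by_label["D"].members == ["D"]

    def test_chain_grouped_with_most_general_label(self):
        dag = OntologyDAG.from_edges([("C", "B"), ("B", "A")])
        groups = group_enriched_terms(dag, {"A", "B", "C"})
        assert len(groups) == 1
        assert groups[0].label == "A"
        assert groups[0].tag == "A"

    def test_no_enriched_terms_empty_list(self, toy_dag):
        assert group_enriched_terms(toy_dag, set()) == []

    def test_groups_partition_enriched_set(self):
        for seed in range(5):
            onto = simulate_ontology(seed=seed)
            res = elim_enrichment(onto.dag, onto.annotations, onto.selected_genes, alpha=0.05)
            enriched = {r.term for r in res if r.enriched}
            groups = group_enriched_terms(onto.dag, enriched)
            members = [t for g in groups for t in g.members]
            assert sorted(members) == sorted(enriched)

    def test_siblings_without_ancestor_path_stay_separate(self, toy_dag):
        groups = group_enriched_terms(toy_dag, {"C", "D"})  # no ancestor relation
        assert len(groups) == 2


class TestClusterGroupEnrichment:
    def _setup(self):
        genes = [f"g{i}" for i in range(40)]
        dag = OntologyDAG.from_edges([("T", "R"), ("U", "R")])
        pairs = [(g, "T") for g in genes[:10]] + [(g, "U") for g in genes]
        ann = AnnotationMap.from_pairs(pairs, dag=dag, propagate=True)
        groups = [
            GOGroup(tag="A", label="T", members=["T"]),
            GOGroup(tag="B", label="U", members=["U"]),
        ]
        return genes, ann, groups

    def test_planted_cluster_group_pair_flagged(self):
        genes, ann, groups = self._setup()
        # cluster 0 is exactly the genes of group A
        assignment = {g: (0 if i < 10 else 1) for i, g in enumerate(genes)}
        table = cluster_group_enrichment(groups, ann, set(genes), assignment)
        cell = table[(table.cluster == 0) & (table.group == "A")].iloc[0]
        assert cell["p_value"] == pytest.approx(
            hypergeom_tail_exact(10, 10, 40, 10), rel=1e-10
        )
        assert cell["significant"] == 1

    def test_group_covering_all_selected_genes_p_one(self):
        genes, ann, groups = self._setup()
        assignment = {g: i % 3 for i, g in enumerate(genes)}
        table = cluster_group_enrichment(groups, ann, set(genes), assignment)
        assert np.all(table.loc[table.group == "B", "p_value"] == 1.0)

    def test_permuted_labels_flag_rate_near_alpha(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(600)]
        dag = OntologyDAG.from_edges([(f"T{i}", "R") for i in range(8)])
        pairs = [
            (g, f"T{i}") for i in range(8) for g in rng.choice(genes, 300, replace=False)
        ]
        ann = AnnotationMap.from_pairs(pairs, dag=dag, propagate=True)
        groups = [GOGroup(tag=chr(65 + i), label=f"T{i}", members=[f"T{i}"]) for i in range(8)]
        rates = []
        for _ in range(30):
            assignment = dict(zip(genes, rng.integers(0, 6, len(genes))))
            table = cluster_group_enrichment(groups, ann, set(genes), assignment)
            rates.append(table["significant"].mean())
        # one-sided tests at 0.05 are conservative but not degenerate
        assert 0.005 <= np.mean(rates) <= 0.065
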