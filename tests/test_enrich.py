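"""Set construction, overlap elimination, dependence-graph scoring and FDR."""

import numpy as np
import pandas as pd
import pytest

from kea import (Association, KinaseSet, build_metadb, build_sets,
                 correct_and_fdr, eliminate_overlaps, enrich_kinases,
                 primary_set_pvalue, rank_score)
from kea.diffexp import RankedList
from kea.enrich import enrich_direction


def ranked_list(sites, direction="over"):
    return RankedList(direction=direction, sites=tuple(sites))


def db_from_pairs(pairs):
    assocs = [
        Association(kinase=k, substrate=s, evidence="experimental",
                    sources=frozenset({"PSP"}))
        for k, s in pairs
    ]
    return build_metadb([assocs])


class TestBuildSets:
    def test_restriction_to_universe(self):
        db = db_from_pairs([("K", f"G{i}_S1") for i in range(10)])
        universe = [f"G{i}_S1_m1" for i in range(3)] + ["X_S9_m1"]
        (s,) = build_sets(db, universe)
        assert len(s) == 3

    def test_small_sets_dropped(self):
        db = db_from_pairs([("K1", "A_S1"), ("K1", "B_S1"),
                            ("K2", "A_S1"), ("K2", "C_S1")])
        sets = build_sets(db, ["A_S1_m1", "B_S1_m1"], min_set_size=2)
        assert [s.name for s in sets] == ["K1"]

    def test_disjoint_universe_is_error(self):
        db = db_from_pairs([("K", "A_S1"), ("K", "B_S1")])
        with pytest.raises(ValueError, match="enough measured substrates"):
            build_sets(db, ["Z_S1_m1", "Z_S2_m1"])


class TestPrimaryPvalue:
    def test_top_block_matches_exact_count(self):
        universe = [f"S{i}" for i in range(10)]
        ranked = ranked_list(universe)
        s = KinaseSet("K", frozenset(universe[:3]))
        p = primary_set_pvalue(ranked, s)
        assert p == pytest.approx(1 / 120, rel=1e-9)

    def test_bottom_block_not_enriched(self):
        universe = [f"S{i}" for i in range(10)]
        s = KinaseSet("K", frozenset(universe[-3:]))
        assert primary_set_pvalue(ranked_list(universe), s) >= 0.5


class TestOverlapElimination:
    def setup_ranked(self):
        # 40 sites; A's 5 members at the very top are the real signal
        universe = [f"S{i}" for i in range(40)]
        return ranked_list(universe), universe

    def test_decoy_superset_is_discarded_with_edge(self):
        ranked, universe = self.setup_ranked()
        a = KinaseSet("A", frozenset(universe[:5]))
        b = KinaseSet("B", frozenset(universe[:5]) | {universe[20]})
        pvals = {s.name: primary_set_pvalue(ranked, s) for s in (a, b)}
        assert pvals["B"] <= 0.01  # significant only through the overlap
        g = eliminate_overlaps([a, b], pvals, ranked)
        assert g.has_edge("A", "B")
        assert g.nodes["A"]["retained"]
        assert not g.nodes["B"]["retained"]
        # direct recomputation confirms B \ A is unremarkable
        from kea.enrich import _pvalue_without

        p_reduced = _pvalue_without(b, a.members, list(ranked.sites), ranked.index())
        assert p_reduced > 0.01

    def test_disjoint_significant_sets_both_retained(self):
        ranked, universe = self.setup_ranked()
        a = KinaseSet("A", frozenset(universe[:4]))
        b = KinaseSet("B", frozenset(universe[4:8]))
        pvals = {s.name: primary_set_pvalue(ranked, s) for s in (a, b)}
        g = eliminate_overlaps([a, b], pvals, ranked)
        assert g.number_of_edges() == 0
        assert g.nodes["A"]["retained"] and g.nodes["B"]["retained"]

    def test_single_significant_set_retained(self):
        ranked, universe = self.setup_ranked()
        a = KinaseSet("A", frozenset(universe[:4]))
        g = eliminate_overlaps([a], {"A": primary_set_pvalue(ranked, a)}, ranked)
        assert list(g.nodes) == ["A"]
        assert g.nodes["A"]["retained"]

    def test_order_independence(self):
        ranked, universe = self.setup_ranked()
        sets = [
            KinaseSet("A", frozenset(universe[:5])),
            KinaseSet("B", frozenset(universe[:5]) | {universe[20]}),
            KinaseSet("C", frozenset(universe[5:9])),
        ]
        pvals = {s.name: primary_set_pvalue(ranked, s) for s in sets}
        g1 = eliminate_overlaps(sets, pvals, ranked)
        g2 = eliminate_overlaps(sets[::-1], pvals, ranked)
        assert dict(g1.nodes(data="retained")) == dict(g2.nodes(data="retained"))
        assert set(g1.edges) == set(g2.edges)


class TestRankScore:
    def test_edgeless_graph_is_uniform(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from("ABCD")
        scores = rank_score(g)
        assert all(v == pytest.approx(0.25, abs=1e-9) for v in scores.values())

    def test_scores_sum_to_one(self):
        import networkx as nx

        g = nx.DiGraph([("A", "B"), ("A", "C"), ("B", "C")])
        assert sum(rank_score(g).values()) == pytest.approx(1.0, abs=1e-9)

    def test_chain_matches_independent_power_iteration(self):
        import networkx as nx

        g = nx.DiGraph([("A", "B"), ("B", "C")])
        scores = rank_score(g, damping=0.85)
        # independent power iteration on the reversed chain C -> B -> A
        nodes = ["A", "B", "C"]
        M = np.zeros((3, 3))
        M[1, 2] = 1.0  # C -> B
        M[0, 1] = 1.0  # B -> A
        v = np.full(3, 1 / 3)
        for _ in range(1000):
            new = np.full(3, (1 - 0.85) / 3)
            new += 0.85 * (M @ v)
            new += 0.85 * v[0] / 3  # dangling node A spreads uniformly
            v = new
        for i, n in enumerate(nodes):
            assert scores[n] == pytest.approx(v[i], abs=1e-8)

    def test_empty_graph(self):
        import networkx as nx

        assert rank_score(nx.DiGraph()) == {}


class TestCorrectAndFdr:
    def test_bonferroni_product_rule_and_monotonicity(self):
        universe = [f"S{i}" for i in range(50)]
        ranked = ranked_list(universe)
        sets = [KinaseSet("A", frozenset(universe[:4])),
                KinaseSet("B", frozenset(universe[10:14]))]
        pvals = {s.name: primary_set_pvalue(ranked, s) for s in sets}
        out = correct_and_fdr(sets, pvals, ranked, n_sets_tested=50,
                              b_null=20, seed=0)
        for k in out.index:
            assert out.loc[k, "corrected_p"] == pytest.approx(
                min(1.0, pvals[k] * 50), rel=1e-12)
            assert out.loc[k, "corrected_p"] >= out.loc[k, "primary_p"]

    def test_low_b_null_warns(self):
        universe = [f"S{i}" for i in range(20)]
        ranked = ranked_list(universe)
        sets = [KinaseSet("A", frozenset(universe[:3]))]
        pvals = {"A": primary_set_pvalue(ranked, sets[0])}
        with pytest.warns(UserWarning, match="unstable"):
            correct_and_fdr(sets, pvals, ranked, b_null=5, seed=0)

    def test_null_pass_rate_matches_nominal_level(self):
        # random rankings: sets passing p <= 0.01 should appear at about
        # 0.01 x n_sets, within 3 SD over replicates
        rng = np.random.default_rng(1)
        n_sets, n_universe, reps = 30, 300, 60
        universe = [f"S{i}" for i in range(n_universe)]
        counts = []
        for _ in range(reps):
            order = list(rng.permutation(universe))
            ranked = ranked_list(order)
            n_pass = 0
            for j in range(n_sets):
                members = frozenset(
                    str(x) for x in rng.choice(universe, size=8, replace=False)
                )
                p = primary_set_pvalue(ranked, KinaseSet(f"K{j}", members))
                n_pass += p <= 0.01
            counts.append(n_pass)
        mean = np.mean(counts)
        expected = 0.01 * n_sets
        sd = np.std(counts, ddof=1) / np.sqrt(reps)
        assert abs(mean - expected) <= max(3 * sd, 0.15)


class TestEndToEnd:
    def test_planted_kinases_recovered(self, planted_run):
        truth = planted_run["truth"]
        over = planted_run["results"]["over"]
        for kinase in truth.active_kinases:
            assert over.loc[kinase, "primary_p"] <= 0.01
            assert over.loc[kinase, "significant"] and over.loc[kinase, "retained"]
        decoys_passing = over[over["significant"]].index.difference(
            truth.active_kinases)
        assert len(decoys_passing) <= 1

    def test_negated_effects_swap_directions(self, planted_run):
        diff = planted_run["diff"]
        neg = diff.copy()
        neg["log2fc"] = -neg["log2fc"]
        res_neg = enrich_kinases(neg, planted_run["db"], b_null=100, seed=11)
        res = planted_run["results"]
        for d, d_neg in (("over", "under"), ("under", "over")):
            a = res[d].drop(columns="direction")
            b = res_neg[d_neg].drop(columns="direction")
            pd.testing.assert_frame_equal(a, b)

    def test_seed_determinism(self, planted_run):
        res2 = enrich_kinases(planted_run["diff"], planted_run["db"],
                              b_null=100, seed=11)
        for d in ("over", "under"):
            pd.testing.assert_frame_equal(planted_run["results"][d], res2[d])
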