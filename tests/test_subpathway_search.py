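import math

import numpy as np
import pytest

from helpers import make_risk, oracle_score, pg_from_edges, verify_greedy_trace
from icds import (IcdsError, SearchParams, Subpathway, activity_score,
                  filter_by_size, find_candidate_subpathways, greedy_expand,
                  induced_diameter, merge_subpathways, select_seeds)
from icds.pathway_io import PathwayGraphSet

SQRT = SearchParams()
MEAN = SearchParams(score_normalization="mean")


class TestSelectSeeds:
    graph = pg_from_edges("P", [("A", "B"), ("B", "C")])

    def test_empty_when_nothing_below_threshold(self):
        risk = make_risk({"A": 1.0, "B": 2.0}, p_s={"A": 0.5, "B": 0.01})
        assert select_seeds(risk, self.graph, 0.001) == []

    def test_ordered_by_decreasing_rs_ties_lexicographic(self):
        risk = make_risk({"A": 3.0, "B": 5.0, "C": 3.0},
                         p_s={"A": 1e-5, "B": 1e-5, "C": 1e-5})
        assert select_seeds(risk, self.graph, 0.001) == ["B", "A", "C"]

    def test_threshold_is_strict(self):
        risk = make_risk({"A": 4.0, "B": 4.0}, p_s={"A": 0.001, "B": 0.0009})
        assert select_seeds(risk, self.graph, 0.001) == ["B"]


class TestActivityScore:
    risk = make_risk({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0, "M": np.nan})

    def test_single_gene_identity(self):
        risk = make_risk({"X": 2.5})
        assert activity_score(["X"], risk, "mean") == 2.5
        assert activity_score(["X"], risk, "sqrt") == 2.5

    def test_mean_normalization(self):
        assert activity_score(["A", "B", "C"], self.risk, "mean") == pytest.approx(2.0)

    def test_sqrt_normalization(self):
        assert activity_score(["A", "B", "C"], self.risk, "sqrt") == pytest.approx(6 / math.sqrt(3))

    def test_missing_rs_excluded_from_n(self):
        assert activity_score(["D", "M"], self.risk, "mean") == pytest.approx(4.0)
        assert activity_score(["D", "M"], self.risk, "sqrt") == pytest.approx(4.0)

    def test_all_missing_is_error(self):
        with pytest.raises(IcdsError):
            activity_score(["M"], self.risk)


class TestGreedyExpand:
    def test_isolated_seed_stays_alone(self):
        graph = pg_from_edges("P", [("B", "C")], extra_nodes=["S"])
        risk = make_risk({"S": 5.0, "B": 1.0, "C": 1.0})
        sub = greedy_expand(graph, "S", risk, SQRT)
        assert sub.genes == ("S",) and sub.score == 5.0

    def test_star_stop_rule_mean_mode(self):
        # seed 5.0 with neighbors 4.9 and 0.0: adding 4.9 gives mean 4.95,
        # which is no 5% improvement over 5.0, so expansion stops at the seed
        graph = pg_from_edges("P", [("S", "L1"), ("S", "L2")])
        risk = make_risk({"S": 5.0, "L1": 4.9, "L2": 0.0})
        sub = greedy_expand(graph, "S", risk, MEAN)
        assert sub.genes == ("S",)
        verify_greedy_trace(graph, "S", risk, MEAN)

    def test_chain_halts_at_max_distance(self):
        graph = pg_from_edges("P", [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])
        risk = make_risk({g: 3.0 for g in "ABCDE"})
        sub = greedy_expand(graph, "C", risk, SQRT)
        # growth is favourable throughout, but diameter 4 is never induced
        assert set(sub.genes) in ({"A", "B", "C", "D"}, {"B", "C", "D", "E"})
        assert induced_diameter(graph, set(sub.genes)) == 3
        verify_greedy_trace(graph, "C", risk, SQRT)

    def test_ties_broken_to_lexicographically_smallest(self):
        graph = pg_from_edges("P", [("M", "A"), ("M", "B")])
        risk = make_risk({"M": 2.0, "A": 2.0, "B": 2.0})
        sub = greedy_expand(graph, "M", risk, SQRT)
        assert sub.genes[1] == "A"

    def test_missing_rs_neighbors_never_added(self):
        graph = pg_from_edges("P", [("S", "X"), ("X", "Y")])
        risk = make_risk({"S": 3.0, "X": np.nan, "Y": 3.0})
        sub = greedy_expand(graph, "S", risk, SQRT)
        assert "X" not in sub.genes

    def test_missing_seed_rs_is_error(self):
        graph = pg_from_edges("P", [("S", "X")])
        risk = make_risk({"S": np.nan, "X": 1.0})
        with pytest.raises(IcdsError, match="missing"):
            greedy_expand(graph, "S", risk, SQRT)

    def test_sign_safe_rule_vs_literal_on_negative_scores(self):
        # with a negative current score the literal rule lowers the bar;
        # the sign-safe default still demands a genuine relative gain
        graph = pg_from_edges("P", [("S", "B")])
        risk = make_risk({"S": -2.0, "B": -1.9})
        stays = greedy_expand(graph, "S", risk, MEAN)
        assert stays.genes == ("S",)
        literal = greedy_expand(graph, "S", risk,
                                SearchParams(score_normalization="mean",
                                             acceptance_rule="literal"))
        assert literal.genes == ("S", "B")

    @pytest.mark.parametrize("graph_seed", range(6))
    def test_random_graph_traces_match_exhaustive_oracle(self, graph_seed, rng):
        import networkx as nx
        g = nx.gnp_random_graph(10, 0.3, seed=graph_seed)
        graph = pg_from_edges("R", [(f"n{a}", f"n{b}") for a, b in g.edges],
                              extra_nodes=[f"n{i}" for i in g.nodes])
        risk = make_risk({n: float(v) for n, v in
                          zip(sorted(graph.nodes), rng.normal(1, 2, len(graph.nodes)))})
        for params in (SQRT, MEAN):
            for seed_gene in sorted(graph.nodes):
                verify_greedy_trace(graph, seed_gene, risk, params)


def _sub(pid, sid, genes, risk, params=SQRT):
    return Subpathway(subpath_id=sid, pathway_id=pid, genes=tuple(genes),
                      score=activity_score(genes, risk, params.score_normalization))


class TestMergeAndFilter:
    risk = make_risk({g: float(i) for i, g in enumerate("ABCDEFG")})

    def test_identical_sets_merge_to_one(self):
        subs = [_sub("P", "P_1", "ABC", self.risk), _sub("P", "P_2", "ABC", self.risk)]
        merged = merge_subpathways(subs, SQRT, self.risk)
        assert len(merged) == 1

    def test_disjoint_sets_untouched(self):
        subs = [_sub("P", "P_1", "AB", self.risk), _sub("P", "P_2", "CD", self.risk)]
        assert len(merge_subpathways(subs, SQRT, self.risk)) == 2

    def test_jaccard_exactly_at_threshold_not_merged(self):
        subs = [_sub("P", "P_1", "ABCD", self.risk), _sub("P", "P_2", "ABCE", self.risk)]
        assert len(merge_subpathways(subs, SQRT, self.risk)) == 2  # 3/5 == 0.6

    def test_just_above_threshold_merges_and_recomputes_score(self):
        subs = [_sub("P", "P_1", "ABCD", self.risk), _sub("P", "P_2", "ABCDE", self.risk)]
        merged = merge_subpathways(subs, SQRT, self.risk)  # 4/5 > 0.6
        assert len(merged) == 1
        assert set(merged[0].genes) == set("ABCDE")
        assert merged[0].score == pytest.approx(
            activity_score(list("ABCDE"), self.risk, "sqrt"))
        assert set(merged[0].merged_from) == {"P_1", "P_2"}

    def test_merge_chains_to_fixed_point(self):
        subs = [_sub("P", "P_1", "ABCD", self.risk),
                _sub("P", "P_2", "ABCDE", self.risk),
                _sub("P", "P_3", "BCDEF", self.risk)]
        merged = merge_subpathways(subs, SQRT, self.risk)
        assert len(merged) == 1 and set(merged[0].genes) == set("ABCDEF")

    @pytest.mark.parametrize("size,kept", [(5, False), (6, True), (99, True), (100, False)])
    def test_size_filter_boundaries(self, size, kept):
        genes = [f"g{i}" for i in range(size)]
        risk = make_risk({g: 1.0 for g in genes})
        sub = _sub("P", "P_1", genes, risk)
        assert bool(filter_by_size([sub], SQRT)) is kept


class TestFindCandidates:
    def _toy12(self):
        # 12-node graph with a planted 7-gene high-risk star module
        module_edges = [("M0", f"M{i}") for i in range(1, 7)]
        bg_edges = [("M0", "B1"), ("B1", "B2"), ("B2", "B3"), ("B3", "B4"), ("B4", "B5")]
        graph = pg_from_edges("path:t01", module_edges + bg_edges)
        rs = {f"M{i}": 4.0 for i in range(7)}
        rs.update({f"B{i}": 0.0 for i in range(1, 6)})
        p_s = {g: (1e-5 if g.startswith("M") else 0.5) for g in rs}
        return PathwayGraphSet([graph]), make_risk(rs, p_s)

    def test_planted_module_is_single_candidate(self):
        graphs, risk = self._toy12()
        cands = find_candidate_subpathways(graphs, risk, SQRT)
        assert len(cands) == 1
        assert set(cands[0].genes) == {f"M{i}" for i in range(7)}
        assert cands[0].subpath_id == "path:t01_1"
        for seed_gene in sorted({f"M{i}" for i in range(7)}):
            verify_greedy_trace(graphs["path:t01"], seed_gene, risk, SQRT)

    def test_no_seeds_contributes_nothing(self):
        graphs, risk = self._toy12()
        risk["p_S"] = 0.5
        assert find_candidate_subpathways(graphs, risk, SQRT) == []

    def test_emitted_scores_consistent_with_recomputation(self):
        graphs, risk = self._toy12()
        for c in find_candidate_subpathways(graphs, risk, SQRT):
            assert c.score == pytest.approx(
                oracle_score(c.genes, risk, "sqrt"), rel=1e-12)

    def test_pre_merge_expansions_respect_distance(self):
        graphs, risk = self._toy12()
        pg = graphs["path:t01"]
        for seed_gene in select_seeds(risk, pg, 0.001):
            sub = greedy_expand(pg, seed_gene, risk, SQRT)
            assert induced_diameter(pg, set(sub.genes)) <= SQRT.max_distance

    def test_determinism(self):
        graphs, risk = self._toy12()
        a = find_candidate_subpathways(graphs, risk, SQRT)
        b = find_candidate_subpathways(graphs, risk, SQRT)
        assert a == b
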