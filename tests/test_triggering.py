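"""Trigger sets, individual probabilities, stars and greedy coverage."""
from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pytest

from airprio.network import Edge, EdgeSign, InteractionNetwork
from airprio.triggering import (TriggerConfig, TriggerResult, greedy_cumulative,
                                individual_scores, leave_one_in_coverage,
                                trigger_set)

from conftest import net_from_nx

FIXED_BREAKS = TriggerConfig(star_breaks=(0.2, 0.4, 0.6, 0.8))


class TestTriggerSet:
    def test_direct_edges_reach_all_effectors(self):
        eff = {"e1", "e2", "e3"}
        net = InteractionNetwork(edges=[Edge("p", e) for e in eff])
        assert trigger_set(net, "p", eff) == frozenset(eff)

    def test_separate_component_triggers_nothing(self):
        net = InteractionNetwork(edges=[Edge("p", "q"), Edge("e1", "e2")])
        assert trigger_set(net, "p", {"e1", "e2"}) == frozenset()

    def test_path_length_bound(self):
        net = InteractionNetwork(edges=[
            Edge("t", "a", directed=True), Edge("a", "e1", directed=True),
            Edge("t", "e2", directed=True)])
        cfg = TriggerConfig(mode="directed", max_path_len=1)
        assert trigger_set(net, "t", {"e1", "e2", "e3"}, cfg) == {"e2"}

    def test_unbounded_undirected_equals_component_intersection(self):
        g = nx.gnp_random_graph(40, 0.05, seed=8)
        net = net_from_nx(g)
        eff = {str(i) for i in range(0, 40, 3)}
        for comp in nx.connected_components(g):
            comp = {str(n) for n in comp}
            protein = sorted(comp)[0]
            assert trigger_set(net, protein, eff) == frozenset(eff & comp)

    def test_sign_aware_requires_net_activating_parity(self):
        # t -| a -> e1 (net inhibiting), t -| b -| e2 (double negative = activating)
        net = InteractionNetwork(edges=[
            Edge("t", "a", directed=True, sign=EdgeSign.INHIBITING),
            Edge("a", "e1", directed=True, sign=EdgeSign.ACTIVATING),
            Edge("t", "b", directed=True, sign=EdgeSign.INHIBITING),
            Edge("b", "e2", directed=True, sign=EdgeSign.INHIBITING)])
        cfg = TriggerConfig(mode="directed", sign_aware=True)
        assert trigger_set(net, "t", {"e1", "e2"}, cfg) == {"e2"}


class TestIndividualScores:
    def test_probability_extremes_map_to_star_extremes(self):
        eff = {"e1", "e2"}
        net = InteractionNetwork(edges=[Edge("p", "e1"), Edge("e1", "e2")],
                                 nodes=["lone"])
        res = individual_scores(net, ["p", "lone"], eff, FIXED_BREAKS)
        by = {r.protein: r for r in res}
        assert by["p"].individual_prob == 1.0 and by["p"].stars == 5
        assert by["lone"].individual_prob == 0.0 and by["lone"].stars == 1

    def test_empty_effector_set_rejected(self):
        net = InteractionNetwork(edges=[Edge("a", "b")])
        with pytest.raises(ValueError):
            individual_scores(net, ["a"], {"ghost"})

    def test_largest_trigger_set_ranks_first(self):
        # one protein reaches strictly more effectors than any other
        eff = [f"e{i}" for i in range(5)]
        edges = [Edge("MAPK13", e) for e in eff]
        edges += [Edge("AKT1", "e0"), Edge("STAT1", "e1"), Edge("STAT1", "e2")]
        net = InteractionNetwork(edges=edges)
        res = individual_scores(net, ["AKT1", "STAT1", "MAPK13"], eff,
                                TriggerConfig(max_path_len=1))
        ranked = sorted(res, key=lambda r: -r.individual_prob)
        assert ranked[0].protein == "MAPK13"
        assert ranked[0].stars == max(r.stars for r in res)

    def test_probability_invariant_to_effector_relabeling(self):
        g = nx.gnp_random_graph(20, 0.15, seed=4)
        net = net_from_nx(g)
        eff = [str(i) for i in range(6)]
        res1 = individual_scores(net, ["10", "11"], eff, FIXED_BREAKS)
        res2 = individual_scores(net, ["10", "11"], list(reversed(eff)), FIXED_BREAKS)
        assert [r.individual_prob for r in res1] == [r.individual_prob for r in res2]

    def test_quintile_breaks_spread_stars(self):
        eff = [f"e{i}" for i in range(5)]
        edges = []
        proteins = []
        for k in range(1, 6):
            p = f"p{k}"
            proteins.append(p)
            edges += [Edge(p, e) for e in eff[:k]]
        net = InteractionNetwork(edges=edges)
        res = individual_scores(net, proteins, eff, TriggerConfig(max_path_len=1))
        stars = {r.protein: r.stars for r in res}
        assert stars["p5"] == 5 and stars["p1"] == 1


def results_from(sets: dict[str, set[str]], n_eff: int) -> list[TriggerResult]:
    return [TriggerResult(protein=p, trigger_set=frozenset(s),
                          individual_prob=len(s) / n_eff)
            for p, s in sets.items()]


class TestGreedyCumulative:
    def test_three_protein_example(self):
        eff = {"e1", "e2", "e3", "e4"}
        res = results_from({"p1": {"e1", "e2"}, "p2": {"e2", "e3"}, "p3": {"e4"}}, 4)
        out = greedy_cumulative(res, eff)
        by = {r.protein: r for r in out}
        assert [by[p].greedy_rank for p in ("p1", "p2", "p3")] == [1, 2, 3]
        assert [by[p].cumulative_pct for p in ("p1", "p2", "p3")] == [50.0, 75.0, 100.0]
        # exhaustive check: no ordering covers more at each prefix than greedy's final
        for perm in permutations(res):
            covered = set()
            for k, r in enumerate(perm, 1):
                covered |= r.trigger_set
            assert len(covered) <= 4

    def test_single_protein_covers_everything(self):
        eff = {"e1", "e2"}
        res = results_from({"all": {"e1", "e2"}, "other": {"e1"}}, 2)
        out = greedy_cumulative(res, eff)
        by = {r.protein: r for r in out}
        assert by["all"].greedy_rank == 1 and by["all"].cumulative_pct == 100.0
        assert by["other"].greedy_rank is None

    def test_all_empty_trigger_sets_rank_nothing(self):
        res = results_from({"a": set(), "b": set()}, 3)
        out = greedy_cumulative(res, {"e1", "e2", "e3"})
        assert all(r.greedy_rank is None for r in out)

    def test_cumulative_monotone_and_conserved(self):
        rng = np.random.default_rng(3)
        eff = {f"e{i}" for i in range(8)}
        for _ in range(30):
            sets = {f"p{j}": set(rng.choice(sorted(eff),
                                            size=rng.integers(0, 6), replace=False))
                    for j in range(6)}
            res = results_from(sets, len(eff))
            out = greedy_cumulative(res, eff)
            ranked = sorted((r for r in out if r.greedy_rank), key=lambda r: r.greedy_rank)
            pcts = [r.cumulative_pct for r in ranked]
            assert pcts == sorted(pcts)
            union = set().union(*sets.values()) & eff
            if ranked:
                assert pcts[-1] == pytest.approx(100 * len(union) / len(eff))

    def test_greedy_at_least_1_minus_1_over_e_of_optimal(self):
        rng = np.random.default_rng(9)
        bound = 1 - 1 / np.e
        for _ in range(40):
            n_eff = int(rng.integers(3, 9))
            eff = {f"e{i}" for i in range(n_eff)}
            sets = {f"p{j}": set(rng.choice(sorted(eff),
                                            size=rng.integers(0, n_eff + 1),
                                            replace=False))
                    for j in range(int(rng.integers(2, 11)))}
            res = results_from(sets, n_eff)
            out = greedy_cumulative(res, eff)
            ranked = sorted((r for r in out if r.greedy_rank), key=lambda r: r.greedy_rank)
            for k in range(1, min(4, len(ranked) + 1)):
                greedy_cov = len(set().union(*(r.trigger_set for r in ranked[:k])))
                best = 0
                for combo in combinations(sets.values(), min(k, len(sets))):
                    best = max(best, len(set().union(*combo)))
                assert greedy_cov >= bound * best - 1e-9

    def test_leave_one_in_coverage_matches_set_sizes(self):
        eff = {"e1", "e2", "e3", "e4"}
        res = results_from({"p1": {"e1", "e2"}, "p2": {"e3"}}, 4)
        cov = leave_one_in_coverage(res, eff)
        assert cov == {"p1": 50.0, "p2": 25.0}

    def test_tie_breaks_prefer_higher_probability_then_symbol(self):
        eff = {"e1", "e2"}
        res = [TriggerResult("zz", frozenset({"e1"}), 0.9),
               TriggerResult("aa", frozenset({"e2"}), 0.5),
               TriggerResult("bb", frozenset({"e2"}), 0.5)]
        out = greedy_cumulative(res, eff)
        by = {r.protein: r for r in out}
        assert by["zz"].greedy_rank == 1       # higher marginal? equal (1 vs 1) -> prob
        assert by["aa"].greedy_rank == 2       # symbol beats bb
        assert by["bb"].greedy_rank is None


class TestConfig:
    def test_bad_star_breaks_rejected(self):
        with pytest.raises(ValueError):
            TriggerConfig(star_breaks=(0.5, 0.4, 0.6, 0.8))
        with pytest.raises(ValueError):
            TriggerConfig(star_breaks=(0.2, 0.4, 0.6))
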