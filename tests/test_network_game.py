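"""Unit and property tests for the network game and the LRI allocation."""

import itertools
import random
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lrinet import (
    CapacityError,
    CoexpressionNetwork,
    DegenerateGameError,
    MicroarrayNetworkGame,
    UnknownGeneError,
    ValidationError,
    check_axioms,
    game_value,
    lri_closed,
    lri_sum,
    position_value_oracle,
    unanimity_value,
)
from lrinet.game import link_shapley

from conftest import WORKED_EDGES, random_connected_network

F = Fraction
WORKED_SCORES = {"1": F(18, 48), "2": F(11, 48), "3": F(11, 48), "4": F(8, 48)}


# ---------------------------------------------------------------------------
# network primitives
# ---------------------------------------------------------------------------


class TestNetwork:
    def test_star_of_hub_gene(self, worked_example):
        assert worked_example.star("1") == {("1", "2"), ("1", "3"), ("1", "4")}

    def test_star_of_leaf_gene(self, worked_example):
        assert worked_example.star("4") == {("1", "4")}

    def test_star_of_isolated_gene_is_empty(self):
        net = CoexpressionNetwork(["1", "2", "5"], [("1", "2")])
        assert net.star("5") == frozenset()
        assert net.active_players == ("1", "2")

    def test_unknown_gene_named_in_error(self, worked_example):
        with pytest.raises(UnknownGeneError, match="XYZ"):
            worked_example.star("XYZ")

    def test_degree_sum_is_twice_edge_count(self, worked_example):
        total = sum(worked_example.degree(n) for n in worked_example.nodes)
        assert total == 2 * worked_example.n_edges

    @pytest.mark.parametrize(
        "nodes,edges,err",
        [
            (["a", "a"], [], ValidationError),
            (["a", "b"], [("a", "a")], ValidationError),
            (["a", "b"], [("a", "b"), ("b", "a")], ValidationError),
            (["a", "b"], [("a", "c")], UnknownGeneError),
        ],
    )
    def test_invalid_construction_rejected(self, nodes, edges, err):
        with pytest.raises(err):
            CoexpressionNetwork(nodes, edges)


# ---------------------------------------------------------------------------
# value function
# ---------------------------------------------------------------------------


class TestValueFunction:
    @pytest.mark.parametrize(
        "star,g,expected",
        [
            ({("1", "4")}, {("1", "4")}, 1),
            ({("1", "2"), ("1", "3"), ("1", "4")}, {("1", "2"), ("1", "3")}, 0),
            (set(), set(), 1),
        ],
    )
    def test_unanimity_examples(self, star, g, expected):
        assert unanimity_value(star, g) == expected

    def test_value_of_empty_and_full_link_set(self, worked_example):
        game = MicroarrayNetworkGame(worked_example)
        assert game.value([]) == 0
        assert game.value(worked_example.edges) == 1

    def test_value_monotone_under_inclusion(self, worked_example):
        game = MicroarrayNetworkGame(worked_example)
        edges = list(worked_example.edges)
        for mask in range(1 << len(edges)):
            sub = [e for k, e in enumerate(edges) if mask >> k & 1]
            v = game.value(sub)
            for k, e in enumerate(edges):
                if not mask >> k & 1:
                    assert game.value(sub + [e]) >= v

    def test_degenerate_game_raises(self):
        net = CoexpressionNetwork(["a", "b"], [])
        with pytest.raises(DegenerateGameError):
            MicroarrayNetworkGame(net).value([])

    def test_unanimity_decomposition_multiplicities_sum_to_n_active(
        self, worked_example
    ):
        game = MicroarrayNetworkGame(worked_example)
        assert sum(game.unanimity_terms.values()) == game.n_active


# ---------------------------------------------------------------------------
# allocations
# ---------------------------------------------------------------------------


class TestAllocations:
    @pytest.mark.parametrize("fn", [lri_closed, lri_sum, position_value_oracle])
    def test_reference_network_scores(self, worked_example, fn):
        table = fn(worked_example)
        assert table.as_dict() == WORKED_SCORES
        assert table.total == 1

    @pytest.mark.parametrize("fn", [lri_closed, lri_sum, position_value_oracle])
    def test_single_edge_splits_evenly(self, fn):
        net = CoexpressionNetwork(["A", "B"], [("A", "B")])
        assert fn(net).as_dict() == {"A": F(1, 2), "B": F(1, 2)}

    def test_star_graph_hub_gets_half(self):
        net = CoexpressionNetwork(
            ["H", "L1", "L2", "L3"], [("H", "L1"), ("H", "L2"), ("H", "L3")]
        )
        scores = lri_closed(net).as_dict()
        assert scores["H"] == F(1, 2)
        assert all(scores[f"L{k}"] == F(1, 6) for k in (1, 2, 3))

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_complete_graph_is_uniform(self, n):
        nodes = [f"g{k}" for k in range(n)]
        net = CoexpressionNetwork(nodes, list(itertools.combinations(nodes, 2)))
        assert set(lri_closed(net).scores) == {F(1, n)}

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_cycle_graph_is_uniform(self, n):
        # 2-regular: every gene scores 1/n
        nodes = [f"g{k}" for k in range(n)]
        edges = [(nodes[k], nodes[(k + 1) % n]) for k in range(n)]
        assert set(lri_closed(CoexpressionNetwork(nodes, edges)).scores) == {F(1, n)}

    def test_isolated_gene_scores_zero_and_can_be_dropped(self):
        net = CoexpressionNetwork(["1", "2", "5"], [("1", "2")])
        table = lri_closed(net)
        assert table.score_of("5") == 0
        dropped = lri_closed(net, include_isolated=False)
        assert "5" not in dropped.genes

    def test_edgeless_network_warns_not_raises(self):
        net = CoexpressionNetwork(["a", "b"], [])
        with pytest.warns(UserWarning, match="no links"):
            table = lri_closed(net)
        assert set(table.scores) == {F(0)}

    def test_link_shapley_of_leaf_edge(self, worked_example):
        game = MicroarrayNetworkGame(worked_example)
        shap = link_shapley(list(worked_example.edges), game.value)
        assert shap[("1", "4")] == F(1, 3)  # gene 4 receives half of this
        assert sum(shap.values()) == 1  # Shapley efficiency

    def test_oracle_cap(self):
        nodes = [f"g{k}" for k in range(18)]
        edges = [(nodes[k], nodes[k + 1]) for k in range(17)]
        with pytest.raises(CapacityError, match="closed form"):
            position_value_oracle(CoexpressionNetwork(nodes, edges))

    def test_triple_equivalence_on_random_networks(self):
        rng = random.Random(1234)
        for _ in range(25):
            net = random_connected_network(rng)
            c = lri_closed(net).as_dict()
            assert lri_sum(net).as_dict() == c
            assert position_value_oracle(net).as_dict() == c

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_efficiency_and_positivity_properties(self, seed):
        net = random_connected_network(random.Random(seed))
        table = lri_closed(net)
        assert table.total == 1
        floor = F(1, 2 * net.n_active)
        assert all(s >= floor for s in table.scores)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_permutation_equivariance(self, seed):
        rng = random.Random(seed)
        net = random_connected_network(rng)
        labels = list(net.nodes)
        perm = labels[:]
        rng.shuffle(perm)
        mapping = dict(zip(labels, perm))
        base = lri_closed(net).as_dict()
        relabeled = lri_closed(net.relabel(mapping)).as_dict()
        assert all(relabeled[mapping[g]] == base[g] for g in labels)


# ---------------------------------------------------------------------------
# axioms & ranking
# ---------------------------------------------------------------------------


class TestAxiomsAndRanking:
    def test_axioms_on_reference_network(self, worked_example):
        report = check_axioms(worked_example, trials=10, seed=0)
        assert report.all_pass
        assert report.details["total"] == 1

    def test_superfluous_link_direct(self, worked_example):
        # evaluating on a supernetwork with the extra link {2,4} leaves
        # every score unchanged
        game = MicroarrayNetworkGame(worked_example)
        players = list(worked_example.edges) + [("2", "4")]
        shap = link_shapley(players, game.value)
        assert shap[("2", "4")] == 0
        for gene, expect in WORKED_SCORES.items():
            got = sum(
                (shap[e] / 2 for e in players if gene in e), F(0)
            )
            assert got == expect

    def test_relabeling_swaps_scores(self, worked_example):
        swapped = worked_example.relabel({"1": "4", "4": "1"})
        scores = lri_closed(swapped).as_dict()
        assert scores["4"] == F(18, 48) and scores["1"] == F(8, 48)

    def test_ranking_ties_share_rank_lexicographic_order(self):
        # two leaves of a path share a score; competition ranking
        net = CoexpressionNetwork(["b", "a", "c"], [("a", "b"), ("b", "c")])
        rows = lri_closed(net).ranked()
        assert [(r, g) for r, g, _, _ in rows] == [(1, "b"), (2, "a"), (2, "c")]

    def test_score_table_dataframe_round_half_and_columns(self, worked_example):
        df = lri_closed(worked_example).to_dataframe(precision=4)
        assert list(df.columns) == ["gene", "lri_exact", "lri_float", "degree", "rank"]
        assert df.iloc[0]["lri_exact"] == "3/8"
        assert df.iloc[0]["lri_float"] == 0.375
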