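"""Network cleaning, construction and reconciliation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from conftest import random_graph_edges
from netlogit import (
    DataFormatError,
    ExpressionMatrix,
    GeneSetCollection,
    GeneUniverse,
    Network,
    build_coexpression_network,
    build_pathway_network,
    clean_network,
    restrict_to_universe,
    vertex_filter,
)

edge_lists = st.lists(
    st.tuples(st.sampled_from("abcdef"), st.sampled_from("abcdef")), max_size=30
)


class TestCleanNetwork:
    def test_self_loops_and_duplicates_collapse(self):
        net = clean_network([("A", "B"), ("B", "A"), ("A", "A"), ("A", "B")])
        assert net.edges == {("A", "B")}

    def test_empty_input_gives_empty_network(self):
        net = clean_network([])
        assert net.n_vertices == 0 and net.n_edges == 0

    def test_vertices_follow_edges(self):
        net = clean_network([("A", "B"), ("B", "C")])
        assert net.vertices == {"A", "B", "C"} and net.n_edges == 2

    def test_declared_isolated_vertices_kept(self):
        net = clean_network([("A", "B")], vertices=["A", "B", "Z"])
        assert "Z" in net.vertices and net.neighbors("Z") == set()

    @given(edge_lists)
    def test_idempotence(self, edges):
        once = clean_network(edges)
        twice = clean_network(once.edges)
        assert once.edges == twice.edges


class TestPathwayNetwork:
    @pytest.mark.parametrize(
        "sets, expected_edges",
        [
            ({"P1": "ABC"}, {("A", "B"), ("A", "C"), ("B", "C")}),
            ({"P1": "AB", "P2": "AB"}, {("A", "B")}),
            ({"P1": "AB", "P2": "BC"}, {("A", "B"), ("B", "C")}),
        ],
    )
    def test_clique_construction(self, sets, expected_edges):
        net = build_pathway_network(GeneSetCollection({k: list(v) for k, v in sets.items()}))
        assert net.edges == expected_edges

    def test_disjoint_sets_edge_count_is_sum_of_cliques(self):
        sets = {"P1": ["a", "b", "c"], "P2": ["d", "e", "f", "g"], "P3": ["h", "i"]}
        net = build_pathway_network(GeneSetCollection(sets))
        assert net.n_edges == 3 + 6 + 1


def _expr(matrix, genes):
    frame = pd.DataFrame(
        np.asarray(matrix, dtype=float),
        index=genes,
        columns=[f"s{i}" for i in range(np.shape(matrix)[1])],
    )
    return ExpressionMatrix(frame)


class TestCoexpressionNetwork:
    def test_identical_profiles_linked(self):
        net = build_coexpression_network(_expr([[1, 2, 3], [1, 2, 3]], ["a", "b"]))
        assert net.edges == {("a", "b")}

    def test_anticorrelated_profiles_not_linked(self):
        net = build_coexpression_network(_expr([[1, 2, 3], [3, 2, 1]], ["a", "b"]))
        assert net.n_edges == 0

    def test_matches_bruteforce_pairwise_pcc(self):
        rng = np.random.default_rng(5)
        values = rng.standard_normal((8, 6))
        genes = [f"g{i}" for i in range(8)]
        net = build_coexpression_network(_expr(values, genes), threshold=0.3)
        expected = set()
        for i in range(8):
            for j in range(i + 1, 8):
                pcc = np.corrcoef(values[i], values[j])[0, 1]
                if pcc > 0.3:
                    expected.add(tuple(sorted((genes[i], genes[j]))))
        assert net.edges == expected

    def test_zero_variance_gene_gets_no_edges(self):
        net = build_coexpression_network(
            _expr([[1, 1, 1], [1, 2, 3], [2, 4, 6]], ["flat", "a", "b"])
        )
        assert net.neighbors("flat") == set()
        assert net.edges == {("a", "b")}

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(9)
        expr = _expr(rng.standard_normal((10, 5)), [f"g{i}" for i in range(10)])
        low = build_coexpression_network(expr, threshold=0.2)
        high = build_coexpression_network(expr, threshold=0.6)
        assert high.edges <= low.edges

    def test_fewer_than_three_samples_rejected(self):
        with pytest.raises(DataFormatError):
            build_coexpression_network(_expr([[1, 2], [2, 1]], ["a", "b"]))


class TestVertexFilter:
    def _nets(self, memberships):
        return [Network(vertices=vs) for vs in memberships]

    def test_four_of_five_kept_three_dropped(self):
        nets = self._nets([["a", "b"], ["a", "b"], ["a", "b"], ["a"], ["z"]])
        assert vertex_filter(nets, min_count=4) == {"a"}

    def test_min_count_one_is_union(self):
        nets = self._nets([["a"], ["b"], ["c"]])
        assert vertex_filter(nets, min_count=1) == {"a", "b", "c"}

    def test_min_count_above_network_count_is_empty_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="netlogit"):
            assert vertex_filter(self._nets([["a"]]), min_count=2) == frozenset()
        assert "min_count" in caplog.text


class TestRestrictToUniverse:
    def test_outside_edges_removed_and_all_universe_genes_present(self):
        universe = GeneUniverse.from_known(["A", "B", "C"], [])
        net = Network([("A", "B"), ("B", "X")])
        restricted = restrict_to_universe(net, universe)
        assert restricted.edges == {("A", "B")}
        assert restricted.vertices == {"A", "B", "C"}

    def test_network_within_universe_unchanged(self):
        universe = GeneUniverse.from_known(["A", "B"], [])
        net = Network([("A", "B")])
        assert restrict_to_universe(net, universe).edges == net.edges

    def test_empty_network_gives_isolated_universe(self):
        universe = GeneUniverse.from_known(["A", "B", "C"], [])
        restricted = restrict_to_universe(Network(), universe)
        assert restricted.n_vertices == 3 and restricted.n_edges == 0


class TestAdjacencyMatrices:
    def test_adjacency_matches_neighbor_sets(self):
        rng = np.random.default_rng(3)
        edges = random_graph_edges(rng, 20, 0.2)
        universe = GeneUniverse.from_known([f"v{i}" for i in range(20)], [])
        net = restrict_to_universe(Network(edges), universe)
        adj = net.adjacency(universe).toarray()
        for g in universe.genes:
            row = set(
                universe.genes[j] for j in np.flatnonzero(adj[universe.index(g)])
            )
            assert row == net.neighbors(g)

    def test_second_order_is_distance_exactly_two(self):
        universe = GeneUniverse.from_known(["A", "B", "C", "D"], [])
        # path A-B-C plus triangle chord B-D-C? use: A-B, B-C, C-D
        net = restrict_to_universe(Network([("A", "B"), ("B", "C"), ("C", "D")]), universe)
        m2 = net.second_order_adjacency(universe).toarray()
        iA, iB, iC, iD = (universe.index(g) for g in "ABCD")
        assert m2[iA, iC] == 1 and m2[iA, iD] == 0 and m2[iA, iB] == 0
        assert m2[iB, iD] == 1 and m2[iB, iB] == 0
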