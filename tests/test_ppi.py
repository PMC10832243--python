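import networkx as nx
import numpy as np
import pytest

from _oracles import brute_betweenness, brute_closeness, brute_degree
from conftest import random_graph
from herbnet.errors import StageError
from herbnet.io import GeneSet, PPINetwork
from herbnet.ppi import (CentralityRecord, betweenness_centrality,
                         centrality_table, closeness_centrality,
                         degree_centrality, induce_network, median_cutoffs,
                         read_centrality_table, select_hub_genes,
                         write_centrality_table)
from herbnet.simulate import SyntheticScenario, gen_ppi_with_planted_hubs


def _net(g):
    return PPINetwork(graph=g, dialect="string_0_1000")


# ---------------------------------------------------------------------------
# induction
# ---------------------------------------------------------------------------

def test_triangle_induced_on_two_nodes_keeps_single_edge():
    g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])
    sub = induce_network(_net(g), {"A", "B"})
    assert set(sub.graph.nodes()) == {"A", "B"}
    assert sub.n_edges == 1


def test_disjoint_gene_set_gives_all_isolates():
    g = nx.Graph([("A", "B")])
    sub = induce_network(_net(g), {"X", "Y", "Z"})
    assert sub.n_edges == 0 and sub.n_nodes == 3 and sub.isolates == 3


def test_empty_gene_set_is_fatal():
    with pytest.raises(StageError):
        induce_network(_net(nx.Graph()), set())


def test_induced_edges_match_pair_filter_oracle():
    rng = np.random.default_rng(8)
    g = random_graph(rng, 40, 0.15)
    subset = set(rng.choice(40, 18, replace=False).tolist())
    sub = induce_network(_net(g), GeneSet("s", subset))
    expected = {frozenset((a, b)) for a, b in g.edges()
                if a in subset and b in subset}
    assert set(map(frozenset, sub.graph.edges())) == expected


# ---------------------------------------------------------------------------
# centralities vs closed forms and brute force
# ---------------------------------------------------------------------------

def test_degree_conventions_on_path(path_graph):
    assert degree_centrality(path_graph, "simple")["B"] == 2
    assert degree_centrality(path_graph, "doubled")["B"] == 4


def test_isolate_has_zero_degree_under_both_conventions():
    g = nx.Graph()
    g.add_node("L")
    for conv in ("simple", "doubled"):
        assert degree_centrality(g, conv)["L"] == 0


def test_handshake_lemma_on_random_graphs():
    rng = np.random.default_rng(9)
    for _ in range(20):
        g = random_graph(rng, int(rng.integers(2, 40)), float(rng.uniform(0, 0.5)))
        deg = degree_centrality(g, "simple")
        assert sum(deg.values()) == 2 * g.number_of_edges()


def test_betweenness_closed_forms():
    path = nx.Graph([("A", "B"), ("B", "C")])
    bc = betweenness_centrality(path)
    assert bc["B"] == pytest.approx(1.0) and bc["A"] == 0.0
    star = nx.star_graph(4)
    bs = betweenness_centrality(star)
    assert bs[0] == pytest.approx(1.0)
    assert all(bs[leaf] == 0.0 for leaf in range(1, 5))


def test_closeness_closed_forms(path_graph):
    cc = closeness_centrality(path_graph)
    assert cc["B"] == pytest.approx(1.0)
    assert cc["A"] == pytest.approx(2 / 3)
    p4 = nx.path_graph(4)
    assert closeness_centrality(p4)[0] == pytest.approx(3 / (1 + 2 + 3))


def test_centralities_match_brute_force_on_random_graphs():
    rng = np.random.default_rng(10)
    for _ in range(25):
        n = int(rng.integers(2, 26))
        g = random_graph(rng, n, float(rng.uniform(0.05, 0.5)))
        bet, clo = betweenness_centrality(g), closeness_centrality(g)
        bb, bcl = brute_betweenness(g), brute_closeness(g)
        deg = degree_centrality(g, "simple")
        bd = brute_degree(g)
        for v in g:
            assert bet[v] == pytest.approx(bb[v], abs=1e-9)
            assert clo[v] == pytest.approx(bcl[v], abs=1e-9)
            assert deg[v] == bd[v]


def test_tree_leaves_have_zero_betweenness_and_hub_closeness_one():
    t = nx.random_labeled_tree(15, seed=4)
    bc = betweenness_centrality(t)
    leaves = [v for v in t if t.degree(v) == 1]
    assert all(bc[v] == 0.0 for v in leaves)
    star = nx.star_graph(6)
    assert closeness_centrality(star)[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# medians and hub selection
# ---------------------------------------------------------------------------

def _table(degrees):
    return [CentralityRecord(f"g{i}", d, 0.5, 0.5) for i, d in enumerate(degrees)]


def test_median_odd_and_even_count_conventions():
    assert median_cutoffs(_table([1, 2, 3]))[0] == 2
    assert median_cutoffs(_table([1, 2, 3, 4]))[0] == 2.5


def test_median_matches_sort_and_pick_oracle():
    rng = np.random.default_rng(14)
    vals = rng.integers(0, 100, 31).tolist()
    got = median_cutoffs(_table(vals))[0]
    s = sorted(vals)
    assert got == s[len(s) // 2]


def test_empty_table_is_fatal():
    with pytest.raises(StageError):
        median_cutoffs([])


def test_identical_rows_strict_empty_inclusive_all():
    table = [CentralityRecord(f"g{i}", 4, 0.2, 0.3) for i in range(6)]
    meds = median_cutoffs(table)
    assert select_hub_genes(table, meds, "strict").hubs == []
    assert len(select_hub_genes(table, meds, "inclusive").hubs) == 6


def test_strict_selection_is_subset_of_inclusive():
    rng = np.random.default_rng(15)
    table = [CentralityRecord(f"g{i}", int(rng.integers(0, 30)),
                              float(rng.uniform(0, 1)), float(rng.uniform(0, 1)))
             for i in range(50)]
    meds = median_cutoffs(table)
    strict = {r.gene for r in select_hub_genes(table, meds, "strict").hubs}
    inclusive = {r.gene for r in select_hub_genes(table, meds, "inclusive").hubs}
    assert strict <= inclusive


def test_planted_hubs_pass_all_three_median_cutoffs():
    scenario = SyntheticScenario(seed=21)
    net, hubs = gen_ppi_with_planted_hubs(scenario)
    table = centrality_table(net, "simple")
    selected = {r.gene for r in select_hub_genes(table).hubs}
    assert set(hubs) <= selected
    ranked = [r.gene for r in select_hub_genes(table).hubs]
    assert set(ranked[:len(hubs)]) == set(hubs)


def test_centrality_table_round_trip_and_ordering(tmp_path):
    g = nx.path_graph(6)
    g = nx.relabel_nodes(g, {i: f"G{i}" for i in g})
    table = centrality_table(g, "doubled")
    assert [r.degree for r in table] == sorted((r.degree for r in table),
                                               reverse=True)
    path = tmp_path / "t.tsv"
    write_centrality_table(table, path)
    assert read_centrality_table(path) == table
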