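import numpy as np
import pytest

from herbnet.errors import StageError
from herbnet.hct import (build_hct, compound_degree_rank, covered_targets,
                         rank_degree_values, subset_network)
from herbnet.io import CompoundTargetLink


def _link(c, g, score=0.9):
    return CompoundTargetLink(c, g, "pharmmapper", score)


def test_compound_target_edges_restricted_to_core():
    net = build_hct({"c1": "H1"}, [_link("c1", "A"), _link("c1", "B")],
                    core_targets={"A"})
    assert net.graph.has_edge("c1", "A")
    assert "B" not in net.graph
    # disease node wired to every core target
    assert net.graph.has_edge(net.disease_label, "A")
    assert net.graph.has_edge(net.formula_label, "H1")


def test_empty_core_set_is_fatal():
    with pytest.raises(StageError):
        build_hct({"c1": "H1"}, [_link("c1", "A")], core_targets=set())


def test_compound_without_herb_assignment_is_fatal():
    with pytest.raises(StageError):
        build_hct({"c1": "H1"}, [_link("c2", "A")], core_targets={"A"})


def test_edge_count_matches_brute_force_filter():
    rng = np.random.default_rng(17)
    comps = [f"c{i}" for i in range(8)]
    genes = [f"G{i}" for i in range(30)]
    links = [_link(comps[rng.integers(8)], genes[rng.integers(30)])
             for _ in range(200)]
    core = set(genes[:12])
    net = build_hct({c: "H" for c in comps}, links, core)
    expected = {(l.compound_id, l.gene_raw) for l in links if l.gene_raw in core}
    got = {(a, b) if a.startswith("c") else (b, a)
           for a, b, d in net.graph.edges(data=True)
           if d.get("etype") == "compound-target"}
    assert got == expected


def test_rank_on_printed_degree_table():
    degrees = {"Luteolin": 48, "Baicalein": 34, "Kaempferol": 31, "Wogonin": 21,
               "Hesperetin": 15, "Isorhamnetin": 14, "Hispidulin": 12,
               "Chrysoeriol": 11, "Diosmetin": 10, "Calycosin": 10,
               "7-O-Methylluteolin": 10, "Kumatakenin": 9, "Odoratin": 9,
               "Pratensein": 8, "Liquiritigenin": 7, "Mosloflavone": 6,
               "Formononetin": 6, "3'-O-Methylorobol": 6, "Medicarpin": 4,
               "Marmesin": 3}
    rank = rank_degree_values(degrees)
    assert rank.median_degree == 10
    assert len(rank.selected) == 8
    assert rank.ranking[0] == ("Luteolin", 48)
    assert set(rank.at_median) == {"Diosmetin", "Calycosin", "7-O-Methylluteolin"}


def test_all_compounds_tied_gives_empty_strict_selection():
    rank = rank_degree_values({f"c{i}": 5 for i in range(4)})
    assert rank.selected == [] and len(rank.at_median) == 4


def test_selection_is_anti_monotone_in_the_median():
    rng = np.random.default_rng(18)
    degrees = {f"c{i}": int(rng.integers(0, 50)) for i in range(30)}
    rank = rank_degree_values(degrees)
    for higher in (rank.median_degree + 1, rank.median_degree + 5):
        bigger = {c for c, d in rank.ranking if d > higher}
        assert bigger <= set(rank.selected)


def test_degree_scope_all_edges_adds_herb_attachment():
    net = build_hct({"c1": "H1"}, [_link("c1", "A"), _link("c1", "B")],
                    core_targets={"A", "B"})
    only_targets = compound_degree_rank(net, "target_edges_only")
    all_edges = compound_degree_rank(net, "all_edges")
    assert dict(only_targets.ranking)["c1"] == 2
    assert dict(all_edges.ranking)["c1"] == 3


def test_rank_without_compounds_is_fatal():
    net = build_hct({"c1": "H1"}, [], core_targets={"A"})
    net.graph.remove_node("c1")
    with pytest.raises(StageError):
        compound_degree_rank(net)


def test_subset_identity_and_errors():
    net = build_hct({"c1": "H1", "c2": "H1"},
                    [_link("c1", "A"), _link("c2", "B")],
                    core_targets={"A", "B"})
    same = subset_network(net, {"c1", "c2"})
    assert set(same.graph.edges()) == set(net.graph.edges())
    with pytest.raises(StageError):
        subset_network(net, set())
    with pytest.raises(StageError):
        subset_network(net, {"c9"})


def test_subset_flags_orphaned_targets_and_matches_filter_oracle():
    rng = np.random.default_rng(19)
    comps = [f"c{i}" for i in range(6)]
    genes = [f"G{i}" for i in range(15)]
    links = [_link(comps[rng.integers(6)], genes[rng.integers(15)])
             for _ in range(60)]
    net = build_hct({c: "H" for c in comps}, links, set(genes))
    keep = set(comps[:3])
    sub = subset_network(net, keep)
    expected_edges = {(l.compound_id, l.gene_raw) for l in links
                      if l.compound_id in keep}
    got = {(a, b) if a.startswith("c") else (b, a)
           for a, b, d in sub.graph.edges(data=True)
           if d.get("etype") == "compound-target"}
    assert got == expected_edges
    expected_orphaned = set(genes) - {l.gene_raw for l in links
                                      if l.compound_id in keep}
    assert set(sub.orphaned_targets) == expected_orphaned
    assert covered_targets(sub) == set(genes) - expected_orphaned


def test_build_is_order_independent():
    links = [_link("c1", "A"), _link("c2", "B"), _link("c1", "B")]
    n1 = build_hct({"c1": "H1", "c2": "H2"}, links, {"A", "B"})
    n2 = build_hct({"c2": "H2", "c1": "H1"}, list(reversed(links)), {"B", "A"})
    assert set(n1.graph.edges()) == set(n2.graph.edges())
    assert dict(n1.graph.nodes(data="ntype")) == dict(n2.graph.nodes(data="ntype"))
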