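"""Disease-herb-compound-target network construction and compound ranking.

The network is a typed graph: a disease node linked to every core target, a
formula root linked to its herbs, herbs linked to their screened compounds,
and compounds linked to the core targets they are predicted to hit.
Compounds are ranked by degree; the main active compounds are those whose
degree strictly exceeds the cohort median.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import StageError
from .io import CompoundTargetLink

NODE_TYPES = ("disease", "formula", "herb", "compound", "target")
EDGE_TYPES = ("disease-target", "formula-herb", "herb-compound", "compound-target")
DEGREE_SCOPES = ("target_edges_only", "all_edges")


@dataclass
class TripartiteNetwork:
    """Typed herb-compound-target graph (node attr ``ntype``, edge ``etype``)."""

    graph: nx.Graph
    disease_label: str
    formula_label: str
    #: targets left with no incident compound after a subset operation
    orphaned_targets: list[str] = field(default_factory=list)

    def nodes_of_type(self, ntype: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True)
                      if d.get("ntype") == ntype)

    @property
    def compounds(self) -> list[str]:
        return self.nodes_of_type("compound")

    @property
    def targets(self) -> list[str]:
        return self.nodes_of_type("target")


@dataclass
class CompoundDegreeRank:
    """Compounds ordered by degree with the median rule's selection."""

    ranking: list[tuple[str, int]]
    median_degree: float
    selected: list[str]
    at_median: list[str] = field(default_factory=list)


def build_hct(
    herb_compound_map: Mapping[str, str | Sequence[str]],
    compound_target_links: Iterable[CompoundTargetLink],
    core_targets: Iterable[str],
    disease_label: str = "disease",
    formula_label: str = "formula",
) -> TripartiteNetwork:
    """Assemble the typed network from screened compounds and core targets.

    Compound-target edges are kept only when the target belongs to
    ``core_targets``; every core target is also wired to the disease node.
    A compound appearing in the links without a herb assignment is fatal.
    """
    core = {t.strip().upper() for t in core_targets}
    if not core:
        raise StageError("core target set is empty; nothing to build")
    links = list(compound_target_links)
    herbs_of: dict[str, list[str]] = {}
    for comp, herbs in herb_compound_map.items():
        herbs_of[comp] = [herbs] if isinstance(herbs, str) else list(herbs)

    g = nx.Graph()
    g.add_node(disease_label, ntype="disease")
    g.add_node(formula_label, ntype="formula")
    for comp, herbs in sorted(herbs_of.items()):
        g.add_node(comp, ntype="compound")
        for herb in herbs:
            g.add_node(herb, ntype="herb")
            g.add_edge(formula_label, herb, etype="formula-herb")
            g.add_edge(herb, comp, etype="herb-compound")
    for t in sorted(core):
        g.add_node(t, ntype="target")
        g.add_edge(disease_label, t, etype="disease-target")
    for link in links:
        if link.compound_id not in herbs_of:
            raise StageError(
                f"compound {link.compound_id!r} has no herb assignment")
        gene = link.gene_raw.strip().upper()
        if gene in core:
            g.add_edge(link.compound_id, gene, etype="compound-target")
    return TripartiteNetwork(graph=g, disease_label=disease_label,
                             formula_label=formula_label)


def compound_degree_rank(
    network: TripartiteNetwork,
    degree_scope: str = "target_edges_only",
) -> CompoundDegreeRank:
    """Rank compounds by degree and select those strictly above the median.

    ``target_edges_only`` counts compound-target edges (target connectivity);
    ``all_edges`` also counts the herb attachment.
    """
    if degree_scope not in DEGREE_SCOPES:
        raise ValueError(f"degree_scope must be one of {DEGREE_SCOPES}")
    compounds = network.compounds
    if not compounds:
        raise StageError("network contains no compounds to rank")
    degrees: dict[str, int] = {}
    for comp in compounds:
        edges = network.graph.edges(comp, data=True)
        if degree_scope == "target_edges_only":
            degrees[comp] = sum(1 for *_, d in edges
                                if d.get("etype") == "compound-target")
        else:
            degrees[comp] = len(list(edges))
    ranking = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))
    median = float(np.median([d for _, d in ranking]))
    selected = [c for c, d in ranking if d > median]
    at_median = [c for c, d in ranking if d == median]
    return CompoundDegreeRank(ranking=ranking, median_degree=median,
                              selected=selected, at_median=at_median)


def rank_degree_values(
    degrees: Mapping[str, int] | Sequence[tuple[str, int]],
) -> CompoundDegreeRank:
    """Apply the median rule directly to a printed (compound, degree) table."""
    items = list(degrees.items()) if isinstance(degrees, Mapping) else list(degrees)
    if not items:
        raise StageError("empty degree table")
    ranking = sorted(items, key=lambda kv: (-kv[1], kv[0]))
    median = float(np.median([d for _, d in ranking]))
    return CompoundDegreeRank(
        ranking=ranking,
        median_degree=median,
        selected=[c for c, d in ranking if d > median],
        at_median=[c for c, d in ranking if d == median],
    )


def subset_network(
    network: TripartiteNetwork,
    compound_subset: Iterable[str],
) -> TripartiteNetwork:
    """Restrict the network to a compound subset (e.g. assay-validated ones).

    Compounds outside the subset are removed with their exclusive edges;
    targets losing every incident compound are flagged in
    ``orphaned_targets`` so downstream stages can re-intersect.
    """
    subset = set(compound_subset)
    if not subset:
        raise StageError("compound subset is empty")
    present = set(network.compounds)
    unknown = subset - present
    if unknown:
        raise StageError(f"unknown compound(s) in subset: {sorted(unknown)}")
    g = network.graph.copy()
    g.remove_nodes_from(present - subset)
    orphaned = [
        t for t in sorted(n for n, d in g.nodes(data=True) if d["ntype"] == "target")
        if not any(d.get("etype") == "compound-target"
                   for *_, d in g.edges(t, data=True))
    ]
    return TripartiteNetwork(graph=g, disease_label=network.disease_label,
                             formula_label=network.formula_label,
                             orphaned_targets=orphaned)


def covered_targets(network: TripartiteNetwork) -> set[str]:
    """Targets with at least one incident compound edge."""
    out = set()
    for a, b, d in network.graph.edges(data=True):
        if d.get("etype") == "compound-target":
            t = a if network.graph.nodes[a]["ntype"] == "target" else b
            out.add(t)
    return out
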