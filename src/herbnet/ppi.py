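"""Induced PPI networks, node centralities, median cutoffs, hub selection.

Hub genes are nodes that exceed the cohort median on all three of degree,
betweenness centrality and closeness centrality.  Degree is reported in two
conventions: ``simple`` (neighbor count, the graph-theoretic degree) and
``doubled`` (twice the neighbor count, matching network viewers that import
each undirected interaction as a pair of directed edges — the convention in
which published hub tables for this kind of analysis are printed).

Betweenness is normalized by (n-1)(n-2)/2 so it lies in [0, 1]; closeness is
computed within each connected component as (k-1)/(sum of distances), with
isolates scoring 0.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import StageError
from .io import GeneSet, PPINetwork

DEGREE_CONVENTIONS = ("simple", "doubled")
STRICTNESS = ("strict", "inclusive")


@dataclass(frozen=True)
class CentralityRecord:
    """One node's row of the centrality table."""

    gene: str
    degree: int
    betweenness: float
    closeness: float

    def __post_init__(self) -> None:
        if self.degree < 0:
            raise ValueError(f"{self.gene}: degree must be >= 0")
        for prop in ("betweenness", "closeness"):
            v = getattr(self, prop)
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValueError(f"{self.gene}: {prop}={v} outside [0, 1]")


@dataclass
class HubSelection:
    medians: tuple[float, float, float]
    strictness: str
    hubs: list[CentralityRecord]


def induce_network(ppi: PPINetwork, gene_set: GeneSet | Iterable[str]) -> PPINetwork:
    """Subnetwork over a gene set; members without qualifying edges stay as
    degree-0 nodes and are counted in ``isolates``."""
    genes = set(gene_set.genes if isinstance(gene_set, GeneSet) else gene_set)
    if not genes:
        raise StageError("cannot induce a network on an empty gene set")
    g = nx.Graph()
    g.add_nodes_from(sorted(genes))
    for a, b, d in ppi.graph.edges(data=True):
        if a in genes and b in genes:
            g.add_edge(a, b, **d)
    isolates = sum(1 for n in g if g.degree(n) == 0)
    return PPINetwork(graph=g, dialect=ppi.dialect, isolates=isolates)


def _graph_of(network: PPINetwork | nx.Graph) -> nx.Graph:
    return network.graph if isinstance(network, PPINetwork) else network


def degree_centrality(network: PPINetwork | nx.Graph,
                      convention: str = "simple") -> dict[str, int]:
    """Neighbor count per node; ``doubled`` = 2x for viewer-style tables."""
    if convention not in DEGREE_CONVENTIONS:
        raise ValueError(f"convention must be one of {DEGREE_CONVENTIONS}")
    g = _graph_of(network)
    factor = 2 if convention == "doubled" else 1
    return {n: factor * g.degree(n) for n in g}


def betweenness_centrality(network: PPINetwork | nx.Graph) -> dict[str, float]:
    """Shortest-path betweenness, normalized by (n-1)(n-2)/2; 0 for n < 3."""
    g = _graph_of(network)
    return nx.betweenness_centrality(g, normalized=True)


def closeness_centrality(network: PPINetwork | nx.Graph,
                         component_policy: str = "within_component") -> dict[str, float]:
    """Within-component closeness (k-1)/sum(distances); isolates score 0."""
    if component_policy != "within_component":
        raise ValueError("only the 'within_component' policy is supported")
    g = _graph_of(network)
    return nx.closeness_centrality(g, wf_improved=False)


def centrality_table(network: PPINetwork | nx.Graph,
                     convention: str = "doubled") -> list[CentralityRecord]:
    """All three centralities per node, sorted by degree desc, then
    betweenness desc, then symbol (the published table ordering)."""
    deg = degree_centrality(network, convention)
    bet = betweenness_centrality(network)
    clo = closeness_centrality(network)
    records = [
        CentralityRecord(gene=n, degree=deg[n],
                         betweenness=min(max(bet[n], 0.0), 1.0),
                         closeness=min(max(clo[n], 0.0), 1.0))
        for n in _graph_of(network)
    ]
    records.sort(key=lambda r: (-r.degree, -r.betweenness, r.gene))
    return records


def median_cutoffs(table: Sequence[CentralityRecord]) -> tuple[float, float, float]:
    """Per-measure median over the full pre-selection table.

    Even-sized tables use the arithmetic mean of the two central order
    statistics.
    """
    if not table:
        raise StageError("cannot take medians of an empty centrality table")
    return (
        float(np.median([r.degree for r in table])),
        float(np.median([r.betweenness for r in table])),
        float(np.median([r.closeness for r in table])),
    )


def select_hub_genes(
    table: Sequence[CentralityRecord],
    medians: tuple[float, float, float] | None = None,
    strictness: str = "strict",
) -> HubSelection:
    """Rows exceeding (strict) or meeting (inclusive) all three cutoffs.

    ``medians`` defaults to :func:`median_cutoffs` of the same table; the
    published analyses pass their printed cutoffs explicitly.
    """
    if strictness not in STRICTNESS:
        raise ValueError(f"strictness must be one of {STRICTNESS}")
    if medians is None:
        medians = median_cutoffs(table)
    dm, bm, cm = medians

    def qualifies(r: CentralityRecord) -> bool:
        if strictness == "strict":
            return r.degree > dm and r.betweenness > bm and r.closeness > cm
        return r.degree >= dm and r.betweenness >= bm and r.closeness >= cm

    hubs = [r for r in table if qualifies(r)]
    hubs.sort(key=lambda r: (-r.degree, -r.betweenness, r.gene))
    return HubSelection(medians=medians, strictness=strictness, hubs=hubs)


# ---------------------------------------------------------------------------
# (de)serialization of centrality tables
# ---------------------------------------------------------------------------

def write_centrality_table(table: Sequence[CentralityRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"gene": r.gene, "degree": r.degree, "betweenness": r.betweenness,
          "closeness": r.closeness} for r in table]
    ).to_csv(path, sep="\t", index=False)


def read_centrality_table(path: str | Path) -> list[CentralityRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        CentralityRecord(gene=str(row.gene), degree=int(row.degree),
                         betweenness=float(row.betweenness),
                         closeness=float(row.closeness))
        for row in df.itertuples(index=False)
    ]
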