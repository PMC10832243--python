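"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of a :class:`SyntheticScenario` (same
scenario, byte-identical output) and returns the generated objects together
with a manifest of planted truths, so recovery can be asserted exactly
(ADME verdicts, Venn overlap) or statistically (hub recovery, planted-term
rank).  Default parameters mirror the scale of a single-formula,
single-disease study: ~100 candidate compounds of which 20 pass screening,
a 290-gene target union, a disease list covering most of a 3,000-gene
universe, a 239-gene planted intersection, and a 200-node core-periphery
interaction graph with 10 planted hubs.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import yaml

from .errors import StageError
from .io import (CompoundRecord, CompoundTargetLink, GeneSet, PPINetwork,
                 write_compound_table, write_gene_list, write_gmt,
                 write_ppi_edges, write_target_links, AnnotationDB,
                 AnnotationTerm)

# per-generator stream tags so each generator is independent of the others
_TAG_COMPOUNDS, _TAG_PPI, _TAG_TARGETS, _TAG_ANNOT = 11, 23, 37, 51


@dataclass(frozen=True)
class PPIScenario:
    """Core-periphery planted-hub graph: hubs attach to every node with
    ``p_within_hub_core``; all remaining pairs with ``p_background``."""

    n_nodes: int = 200
    n_planted_hubs: int = 10
    p_within_hub_core: float = 0.5
    p_background: float = 0.02


@dataclass(frozen=True)
class AnnotationScenario:
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 80)
    n_planted_terms: int = 1
    planted_odds: float = 20.0
    # planted terms get a fixed size rather than a sampled one so the
    # planted signal carries enough hits to be identifiable; a small term
    # cannot reach significance no matter how strongly it is enriched
    planted_term_size: int = 60


@dataclass(frozen=True)
class SyntheticScenario:
    seed: int = 0
    # compound table
    n_compounds: int = 100
    pass_fraction: float = 0.2
    herbs: tuple[tuple[str, float], ...] = (("AM", 0.75), ("AG", 0.05), ("TK", 0.20))
    # targets / disease
    gene_universe_size: int = 3000
    target_union_size: int = 290
    target_degree_mean: float = 13.0
    n_noise_links: int = 150
    disease_set_size: int = 2400
    planted_overlap_size: int = 239
    disease_sources: tuple[str, ...] = ("diseasedb_a", "diseasedb_b", "diseasedb_c")
    ppi: PPIScenario = field(default_factory=PPIScenario)
    annotation: AnnotationScenario = field(default_factory=AnnotationScenario)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pass_fraction <= 1.0:
            raise StageError("pass_fraction must lie in [0, 1]")
        if self.target_union_size > self.gene_universe_size:
            raise StageError("target union cannot exceed the gene universe")
        if self.planted_overlap_size > min(self.target_union_size,
                                           self.disease_set_size):
            raise StageError("planted overlap exceeds one of its parent sets")
        if (self.disease_set_size - self.planted_overlap_size
                > self.gene_universe_size - self.target_union_size):
            raise StageError("disease set does not fit the universe outside "
                             "the target union")

    def rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, tag])


def _universe(scenario: SyntheticScenario) -> list[str]:
    width = len(str(scenario.gene_universe_size - 1))
    return [f"G{i:0{width}d}" for i in range(scenario.gene_universe_size)]


# ---------------------------------------------------------------------------
# compounds
# ---------------------------------------------------------------------------

# property ranges bracketing realistic flavonoid-like values for passers
_PASS_RANGES = {
    "mw": (240.0, 320.0), "alogp": (1.0, 3.0), "hdon": (1, 4), "hacc": (4, 7),
    "ob": (30.0, 75.0), "caco2": (0.1, 1.0), "dl": (0.18, 0.35), "rbn": (1, 3),
}
# a failing compound violates exactly one criterion, drawn from these ranges
_FAIL_RANGES = {
    "mw": (510.0, 800.0), "alogp": (5.1, 8.0), "hdon": (5, 8), "hacc": (10, 14),
    "ob": (5.0, 29.5), "caco2": (-1.5, -0.4), "dl": (0.02, 0.17), "rbn": (11, 15),
}
_INT_PROPS = ("hdon", "hacc", "rbn")


def _draw(rng: np.random.Generator, prop: str, ranges) -> float | int:
    lo, hi = ranges[prop]
    if prop in _INT_PROPS:
        return int(rng.integers(lo, hi + 1))
    return round(float(rng.uniform(lo, hi)), 2)


def gen_compound_table(
    scenario: SyntheticScenario,
) -> tuple[list[CompoundRecord], dict[str, bool]]:
    """Compound table in which exactly round(n * pass_fraction) records
    satisfy the default oral-activity criteria by construction.

    Failers violate exactly one randomly chosen criterion, so every verdict
    branch of the screen is exercised.  The manifest maps compound id to the
    intended verdict.
    """
    n = scenario.n_compounds
    n_pass = round(n * scenario.pass_fraction)
    if not 0 <= n_pass <= n:
        raise StageError(f"infeasible pass fraction {scenario.pass_fraction}")
    rng = scenario.rng(_TAG_COMPOUNDS)
    herb_names = [h for h, _ in scenario.herbs]
    herb_w = np.array([w for _, w in scenario.herbs], dtype=float)
    herb_w = herb_w / herb_w.sum()

    status = np.array([True] * n_pass + [False] * (n - n_pass))
    rng.shuffle(status)
    records, manifest = [], {}
    props = list(_PASS_RANGES)
    for i, passes in enumerate(status):
        cid = f"{90000000 + i}"
        values = {p: _draw(rng, p, _PASS_RANGES) for p in props}
        if not passes:
            bad = props[int(rng.integers(len(props)))]
            values[bad] = _draw(rng, bad, _FAIL_RANGES)
        herb = herb_names[int(rng.choice(len(herb_names), p=herb_w))]
        records.append(CompoundRecord(compound_id=cid, name=f"CMP{i:04d}",
                                      herb_source=herb, **values))
        manifest[cid] = bool(passes)
    return records, manifest


# ---------------------------------------------------------------------------
# PPI graph with planted hubs
# ---------------------------------------------------------------------------

def gen_ppi_with_planted_hubs(
    scenario: SyntheticScenario,
    node_labels: Sequence[str] | None = None,
) -> tuple[PPINetwork, list[str]]:
    """Core-periphery random graph; returns the network and the planted hubs.

    Hubs are wired to every other node with probability
    ``p_within_hub_core``; remaining pairs with ``p_background``.  Edge
    scores are uniform over (700, 1000] in the STRING dialect, i.e. the
    graph is already at post-threshold confidence.
    """
    p = scenario.ppi
    if p.n_planted_hubs >= p.n_nodes:
        raise StageError("need fewer planted hubs than nodes")
    if p.p_within_hub_core <= p.p_background:
        raise StageError("hub wiring probability must exceed the background; "
                         "the planting is unidentifiable otherwise")
    rng = scenario.rng(_TAG_PPI)
    if node_labels is None:
        width = len(str(p.n_nodes - 1))
        nodes = [f"N{i:0{width}d}" for i in range(p.n_nodes)]
    else:
        nodes = list(node_labels)
        if len(nodes) != p.n_nodes:
            raise StageError(f"need {p.n_nodes} node labels, got {len(nodes)}")
    hub_idx = set(rng.choice(p.n_nodes, size=p.n_planted_hubs, replace=False).tolist())
    hubs = sorted(nodes[i] for i in hub_idx)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i in range(p.n_nodes):
        for j in range(i + 1, p.n_nodes):
            prob = (p.p_within_hub_core if (i in hub_idx or j in hub_idx)
                    else p.p_background)
            if rng.random() < prob:
                g.add_edge(nodes[i], nodes[j],
                           score=float(rng.integers(701, 1001)))
    return PPINetwork(graph=g, dialect="string_0_1000"), hubs


# ---------------------------------------------------------------------------
# disease genes and compound-target links with a planted Venn overlap
# ---------------------------------------------------------------------------

def gen_disease_and_targets(
    scenario: SyntheticScenario,
) -> tuple[GeneSet, list[CompoundTargetLink], dict]:
    """Disease gene set and scored compound-target links such that the
    threshold-filtered target union intersects the disease set in exactly
    ``planted_overlap_size`` genes."""
    rng = scenario.rng(_TAG_TARGETS)
    universe = _universe(scenario)
    compounds, manifest_cmp = gen_compound_table(scenario)
    passers = [r.compound_id for r in compounds if manifest_cmp[r.compound_id]]
    if not passers:
        raise StageError("scenario yields no passing compounds to carry targets")

    union = sorted(rng.choice(universe, size=scenario.target_union_size,
                              replace=False).tolist())
    sources = ("pharmmapper", "swisstarget", "stitch")
    links: list[CompoundTargetLink] = []
    # every union gene gets at least one qualifying link
    for gene in union:
        comp = passers[int(rng.integers(len(passers)))]
        links.append(CompoundTargetLink(
            compound_id=comp, gene_raw=gene,
            source_db=sources[int(rng.integers(3))],
            score=float(rng.uniform(0.7001, 1.0))))
    # extra qualifying links per compound (target degree distribution)
    for comp in passers:
        extra = int(rng.poisson(scenario.target_degree_mean))
        for gene in rng.choice(union, size=min(extra, len(union)),
                               replace=False):
            links.append(CompoundTargetLink(
                compound_id=comp, gene_raw=str(gene),
                source_db=sources[int(rng.integers(3))],
                score=float(rng.uniform(0.7001, 1.0))))
    # sub-threshold noise links exercising the score filter
    for _ in range(scenario.n_noise_links):
        links.append(CompoundTargetLink(
            compound_id=passers[int(rng.integers(len(passers)))],
            gene_raw=universe[int(rng.integers(len(universe)))],
            source_db=sources[int(rng.integers(3))],
            score=float(rng.uniform(0.0, 0.7))))

    overlap = sorted(rng.choice(union, size=scenario.planted_overlap_size,
                                replace=False).tolist())
    outside = sorted(set(universe) - set(union))
    rest = rng.choice(outside,
                      size=scenario.disease_set_size - scenario.planted_overlap_size,
                      replace=False).tolist()
    disease_genes = set(overlap) | set(rest)
    # split across pseudo-repositories (with overlap between them, like real
    # disease databases) for union_disease_genes-style ingestion
    per_source: dict[str, set[str]] = {s: set() for s in scenario.disease_sources}
    src_names = list(scenario.disease_sources)
    for g in sorted(disease_genes):
        k = 1 + int(rng.integers(len(src_names)))
        for s in rng.choice(src_names, size=k, replace=False):
            per_source[str(s)].add(g)
    gene_prov = {g: tuple(sorted(s for s in per_source if g in per_source[s]))
                 for g in disease_genes}
    disease = GeneSet(name="disease_genes", genes=disease_genes,
                      provenance=src_names, gene_provenance=gene_prov)
    manifest = {
        "target_union_size": scenario.target_union_size,
        "planted_overlap_size": scenario.planted_overlap_size,
        "overlap_genes": overlap,
        "union_genes": union,
        "per_source_sizes": {s: len(v) for s, v in per_source.items()},
        "per_source_lists": {s: sorted(v) for s, v in per_source.items()},
    }
    return disease, links, manifest


# ---------------------------------------------------------------------------
# annotation databases with planted enriched terms
# ---------------------------------------------------------------------------

def gen_annotation_with_planted_terms(
    scenario: SyntheticScenario,
    query: Sequence[str],
) -> tuple[AnnotationDB, dict]:
    """GMT-style annotation database in which ``n_planted_terms`` terms
    over-sample the query genes at odds ``planted_odds``.

    With odds 1 no term is enriched beyond the null rate (used for
    calibration runs)."""
    a = scenario.annotation
    if a.n_planted_terms > 0 and a.planted_odds <= 1.0:
        raise StageError("planted enrichment odds must exceed 1")
    lo, hi = a.term_size_range
    universe = _universe(scenario)
    if max(hi, a.planted_term_size) > len(universe):
        raise StageError("term sizes exceed the gene universe")
    if a.planted_term_size < 1:
        raise StageError("planted term size must be positive")
    rng = scenario.rng(_TAG_ANNOT)
    qset = [g for g in universe if g in set(query)]
    weights = np.ones(len(universe))
    qmask = np.isin(universe, qset)
    terms: list[AnnotationTerm] = []
    planted_ids: list[str] = []
    expected_hits: dict[str, float] = {}
    for t in range(a.n_terms):
        size = int(rng.integers(lo, hi + 1))
        planted = t < a.n_planted_terms
        if planted:
            size = a.planted_term_size
        if planted:
            w = weights.copy()
            w[qmask] = a.planted_odds
            w = w / w.sum()
            members = rng.choice(universe, size=size, replace=False, p=w)
        else:
            members = rng.choice(universe, size=size, replace=False)
        term_id = f"T{t:04d}"
        if planted:
            planted_ids.append(term_id)
            nq = int(qmask.sum())
            total_w = nq * a.planted_odds + (len(universe) - nq)
            expected_hits[term_id] = size * nq * a.planted_odds / total_w
        terms.append(AnnotationTerm(term_id=term_id, term_name=f"term {t}",
                                    namespace="KEGG",
                                    genes=frozenset(str(m) for m in members)))
    db = AnnotationDB(terms=terms, background=set(universe))
    manifest = {"planted_terms": planted_ids, "expected_hits": expected_hits,
                "query_size_in_universe": int(qmask.sum())}
    return db, manifest


# ---------------------------------------------------------------------------
# full input bundle on disk
# ---------------------------------------------------------------------------

def write_scenario_bundle(scenario: SyntheticScenario, outdir: str | Path) -> dict:
    """Write every pipeline input for a scenario to ``outdir``.

    The interaction graph is generated over the planted overlap genes (the
    set the pipeline will induce on) with the scenario's planted hubs, and
    the annotation database is planted around those hubs, so the full run
    has a known answer at every stage.  Returns the combined manifest, also
    saved as ``manifest.json`` beside the inputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    compounds, cmp_manifest = gen_compound_table(scenario)
    disease, links, tgt_manifest = gen_disease_and_targets(scenario)
    overlap = tgt_manifest["overlap_genes"]
    ppi_scenario = dataclasses.replace(
        scenario, ppi=dataclasses.replace(scenario.ppi, n_nodes=len(overlap)))
    ppi, hubs = gen_ppi_with_planted_hubs(ppi_scenario, node_labels=overlap)
    # terms are planted around the core target set: any hub subset the
    # pipeline selects from it will recover them
    annot, ann_manifest = gen_annotation_with_planted_terms(scenario, query=overlap)

    write_compound_table(compounds, outdir / "compounds.tsv")
    write_target_links(links, outdir / "target_links.tsv")
    for src, genes in tgt_manifest["per_source_lists"].items():
        write_gene_list(genes, outdir / f"disease_{src}.txt")
    write_ppi_edges(ppi, outdir / "ppi_edges.tsv")
    write_gmt(annot, outdir / "annotation.gmt")
    (outdir / "scenario.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(scenario), sort_keys=True))
    manifest = {
        "adme_verdicts": cmp_manifest,
        "n_passing": sum(cmp_manifest.values()),
        "target_union_size": tgt_manifest["target_union_size"],
        "planted_overlap_size": tgt_manifest["planted_overlap_size"],
        "overlap_genes": overlap,
        "planted_hubs": hubs,
        "planted_terms": ann_manifest["planted_terms"],
        "disease_files": [f"disease_{s}.txt" for s in tgt_manifest["per_source_lists"]],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
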