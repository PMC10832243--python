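"""Config-driven orchestration of the full inference chain.

Stage order: ADME screen -> target aggregation -> disease-gene union ->
Venn intersection -> induced PPI network -> centralities -> hub selection ->
herb-compound-target network and compound ranking -> over-representation
analysis.  Every intermediate table is written to the output directory and
every count in the run report is recomputable from those tables.  A second
entry point repeats the chain on a compound subset (e.g. the assay-validated
compounds), writing to a sibling directory.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .adme import AdmeCriteria, Criterion, screen_compounds, write_verdict_table
from .enrich import enrich_gene_set, write_enrichment_table
from .errors import StageError
from .hct import build_hct, compound_degree_rank, subset_network
from .io import (GeneSet, read_compound_table, read_gene_list, read_gmt,
                 read_ppi_edges, read_symbol_map, read_target_links,
                 write_compound_table, write_gene_list, write_network)
from .ppi import (centrality_table, induce_network, median_cutoffs,
                  select_hub_genes, write_centrality_table)
from .targets import aggregate_targets, intersect_targets, union_disease_genes

log = logging.getLogger("herbnet.pipeline")

STAGES = ("screen", "aggregate", "intersect", "induce", "centralities",
          "hubs", "hct", "enrich")


@dataclass
class PipelineConfig:
    """All inputs, thresholds and policy flags for one run."""

    compounds: str
    target_links: str
    disease_lists: dict[str, str]
    ppi_edges: str
    annotations: dict[str, str]            # namespace -> GMT path
    outdir: str = "herbnet_run"
    symbol_map: str | None = None
    adme_overrides: dict[str, tuple[str, float]] = field(default_factory=dict)
    missing_policy: str = "fail"
    per_source_thresholds: dict[str, float] = field(default_factory=dict)
    ppi_dialect: str = "string_0_1000"
    ppi_min_score: float = 700.0
    degree_convention: str = "doubled"
    hub_strictness: str = "strict"
    degree_scope: str = "target_edges_only"
    enrichment_alpha: float = 0.001
    disease_label: str = "disease"
    formula_label: str = "formula"
    compound_subset: list[str] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def validate(self) -> None:
        paths = [self.compounds, self.target_links, self.ppi_edges,
                 *self.disease_lists.values(), *self.annotations.values()]
        if self.symbol_map:
            paths.append(self.symbol_map)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise StageError(f"config references missing file(s): {missing}")

    def criteria(self) -> AdmeCriteria:
        crit = AdmeCriteria(missing_policy=self.missing_policy)
        if self.adme_overrides:
            merged = dict(crit.criteria)
            for prop, (op, thr) in self.adme_overrides.items():
                merged[prop] = Criterion(op, float(thr))
            crit = AdmeCriteria(criteria=merged, missing_policy=self.missing_policy)
        return crit


@dataclass
class RunReport:
    config: dict
    version: str = __version__
    counts: dict = field(default_factory=dict)
    medians: tuple[float, float, float] | None = None
    stage_seconds: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def _log_decision(name: str, value) -> None:
    log.info("decision %s=%r", name, value)


def run_pipeline(config: PipelineConfig,
                 _compound_subset: Sequence[str] | None = None) -> RunReport:
    """Execute all stages; identical config + inputs give identical outputs."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=dataclasses.asdict(config))
    for flag in ("hub_strictness", "degree_convention", "degree_scope",
                 "missing_policy", "ppi_dialect"):
        _log_decision(flag, getattr(config, flag))

    stage = STAGES[0]
    try:
        symbol_map = (read_symbol_map(config.symbol_map)
                      if config.symbol_map else None)

        # ---- screen ----------------------------------------------------
        t0 = time.perf_counter()
        records = read_compound_table(config.compounds)
        screen = screen_compounds(records, config.criteria())
        passers = screen.passing
        if _compound_subset is not None:
            wanted = set(_compound_subset)
            have = {r.compound_id for r in passers} | {r.name for r in passers}
            unknown = wanted - have
            if unknown:
                raise StageError(f"subset compounds not among passers: "
                                 f"{sorted(unknown)}")
            passers = [r for r in passers
                       if r.compound_id in wanted or r.name in wanted]
            if not passers:
                raise StageError("compound subset is empty after restriction")
        write_compound_table(passers, outdir / "passing_compounds.tsv")
        write_verdict_table(screen, outdir / "adme_verdicts.tsv")
        report.counts["candidates"] = len(records)
        report.counts["passing_compounds"] = len(passers)
        report.counts["per_herb"] = {}
        for r in passers:
            report.counts["per_herb"][r.herb_source] = \
                report.counts["per_herb"].get(r.herb_source, 0) + 1
        report.stage_seconds[stage] = time.perf_counter() - t0

        # ---- aggregate targets -----------------------------------------
        stage = "aggregate"
        t0 = time.perf_counter()
        passing_ids = {r.compound_id for r in passers}
        links = [l for l in read_target_links(config.target_links)
                 if l.compound_id in passing_ids]
        formula_targets = aggregate_targets(
            links, config.per_source_thresholds or None, symbol_map)
        write_gene_list(formula_targets.genes, outdir / "formula_targets.txt")
        report.counts["target_union"] = len(formula_targets)
        report.stage_seconds[stage] = time.perf_counter() - t0

        # ---- intersect with disease genes ------------------------------
        stage = "intersect"
        t0 = time.perf_counter()
        disease = union_disease_genes(
            {name: read_gene_list(path)
             for name, path in config.disease_lists.items()},
            symbol_map)
        venn = intersect_targets(formula_targets, disease)
        venn.to_json(outdir / "venn.json")
        core = venn.members_intersection
        if not core.genes:
            raise StageError("empty intersection between formula targets and "
                             "disease genes")
        report.counts["disease_union"] = len(disease)
        report.counts["venn_intersection"] = venn.size_intersection
        report.stage_seconds[stage] = time.perf_counter() - t0

        # ---- induce PPI -------------------------------------------------
        stage = "induce"
        t0 = time.perf_counter()
        ppi = read_ppi_edges(config.ppi_edges, config.ppi_dialect,
                             config.ppi_min_score)
        induced = induce_network(ppi, core)
        write_network(induced.graph, outdir / "ppi_induced.sif", "sif")
        report.counts["ppi_nodes"] = induced.n_nodes
        report.counts["ppi_edges"] = induced.n_edges
        report.counts["ppi_isolates"] = induced.isolates
        report.stage_seconds[stage] = time.perf_counter() - t0

        # ---- centralities & hubs ----------------------------------------
        stage = "centralities"
        t0 = time.perf_counter()
        table = centrality_table(induced, config.degree_convention)
        write_centrality_table(table, outdir / "centrality.tsv")
        report.stage_seconds[stage] = time.perf_counter() - t0

        stage = "hubs"
        t0 = time.perf_counter()
        medians = median_cutoffs(table)
        selection = select_hub_genes(table, medians, config.hub_strictness)
        write_centrality_table(selection.hubs, outdir / "hubs.tsv")
        (outdir / "hubs.json").write_text(json.dumps({
            "medians": {"degree": medians[0], "betweenness": medians[1],
                        "closeness": medians[2]},
            "strictness": selection.strictness,
            "hubs": [r.gene for r in selection.hubs],
        }, indent=2))
        hub_genes = [r.gene for r in selection.hubs]
        report.medians = medians
        report.counts["hub_genes"] = len(hub_genes)
        report.stage_seconds[stage] = time.perf_counter() - t0

        # ---- herb-compound-target network -------------------------------
        stage = "hct"
        t0 = time.perf_counter()
        herb_map = {r.compound_id: r.herb_source for r in passers}
        thresholds = dict(config.per_source_thresholds)
        qualifying = [l for l in links
                      if l.score > thresholds.get(l.source_db, 0.7)]
        hct_net = build_hct(herb_map, qualifying, hub_genes,
                            config.disease_label, config.formula_label)
        write_network(hct_net.graph, outdir / "hct.sif", "sif")
        rank = compound_degree_rank(hct_net, config.degree_scope)
        with open(outdir / "compound_rank.tsv", "w", encoding="utf-8") as fh:
            fh.write("compound\tdegree\tselected\n")
            for comp, deg in rank.ranking:
                fh.write(f"{comp}\t{deg}\t{comp in set(rank.selected)}\n")
        report.counts["compound_degree_median"] = rank.median_degree
        report.counts["selected_compounds"] = len(rank.selected)
        report.stage_seconds[stage] = time.perf_counter() - t0

        # ---- enrichment --------------------------------------------------
        stage = "enrich"
        t0 = time.perf_counter()
        n_significant = 0
        for namespace, gmt_path in sorted(config.annotations.items()):
            db = read_gmt(gmt_path, namespace=namespace)
            results = enrich_gene_set(hub_genes, db,
                                      alpha=config.enrichment_alpha)
            write_enrichment_table(results,
                                   outdir / f"enrichment_{namespace}.tsv")
            n_significant += len(results)
        report.counts["significant_terms"] = n_significant
        report.stage_seconds[stage] = time.perf_counter() - t0
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    report.to_json(outdir / "report.json")
    return report


def run_subset_reanalysis(config: PipelineConfig,
                          compound_subset: Sequence[str]) -> RunReport:
    """Re-run every stage restricted to a compound subset.

    Targets, the Venn intersection, the induced network, medians, hubs and
    enrichment are all re-derived; outputs land in ``<outdir>_subset``.
    """
    if not compound_subset:
        raise StageError("compound subset must not be empty")
    sub_config = dataclasses.replace(
        config, outdir=str(Path(config.outdir).with_name(
            Path(config.outdir).name + "_subset")))
    return run_pipeline(sub_config, _compound_subset=list(compound_subset))
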