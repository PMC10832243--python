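"""Target aggregation across prediction sources and disease-gene intersection.

Compound-target predictions from several databases (each with a confidence
score on its native [0, 1] scale) are filtered at a per-source threshold
(strictly greater, default 0.7 for every source) and unioned into a single
normalized gene set.  Disease gene lists from several repositories are
unioned, and the intersection of the two unions is the putative set of
disease-relevant targets of the formula.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import SchemaError
from .io import CompoundTargetLink, GeneSet, SymbolMap, normalize_symbols

DEFAULT_THRESHOLD = 0.7


@dataclass
class VennReport:
    """Sizes and members of a two-set intersection (the Venn diagram row)."""

    size_a: int
    size_b: int
    size_intersection: int
    members_intersection: GeneSet

    def __post_init__(self) -> None:
        assert self.size_intersection <= min(self.size_a, self.size_b)
        assert len(self.members_intersection.genes) == self.size_intersection

    def to_json(self, path: str | Path) -> None:
        payload = {
            "size_a": self.size_a,
            "size_b": self.size_b,
            "size_intersection": self.size_intersection,
            "members": self.members_intersection.sorted(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def aggregate_targets(
    links: Iterable[CompoundTargetLink],
    per_source_thresholds: Mapping[str, float] | None = None,
    symbol_map: SymbolMap | None = None,
    name: str = "formula_targets",
) -> GeneSet:
    """Union of targets whose score is strictly above its source's threshold.

    Per-gene provenance records which prediction sources contributed each
    symbol after normalization.
    """
    links = list(links)
    thresholds = dict(per_source_thresholds or {})
    present = {l.source_db for l in links}
    for src in present:
        thresholds.setdefault(src, DEFAULT_THRESHOLD)
    unknown = present - set(thresholds)
    if unknown:
        raise SchemaError(f"no threshold defined for source(s) {sorted(unknown)}")

    gene_sources: dict[str, set[str]] = {}
    for link in links:
        if link.score > thresholds[link.source_db]:
            normalized, _ = normalize_symbols([link.gene_raw], symbol_map)
            for gene in normalized:
                gene_sources.setdefault(gene, set()).add(link.source_db)
    return GeneSet(
        name=name,
        genes=set(gene_sources),
        provenance=sorted({s for srcs in gene_sources.values() for s in srcs}),
        gene_provenance={g: tuple(sorted(s)) for g, s in gene_sources.items()},
    )


def union_disease_genes(
    gene_lists: Mapping[str, Sequence[str]],
    symbol_map: SymbolMap | None = None,
    name: str = "disease_genes",
) -> GeneSet:
    """Normalized union of disease gene lists with per-source provenance."""
    if not gene_lists:
        raise SchemaError("at least one disease gene list is required")
    gene_sources: dict[str, set[str]] = {}
    for source, genes in gene_lists.items():
        normalized, _ = normalize_symbols(genes, symbol_map)
        for g in normalized:
            gene_sources.setdefault(g, set()).add(source)
    return GeneSet(
        name=name,
        genes=set(gene_sources),
        provenance=sorted(gene_lists),
        gene_provenance={g: tuple(sorted(s)) for g, s in gene_sources.items()},
    )


def intersect_targets(formula_targets: GeneSet, disease_genes: GeneSet) -> VennReport:
    """Commutative intersection of the formula-target and disease gene sets."""
    inter = formula_targets.genes & disease_genes.genes
    assert len(inter) <= min(len(formula_targets), len(disease_genes))
    members = GeneSet(
        name=f"{formula_targets.name}&{disease_genes.name}",
        genes=set(inter),
        provenance=sorted(set(formula_targets.provenance)
                          | set(disease_genes.provenance)),
    )
    return VennReport(
        size_a=len(formula_targets),
        size_b=len(disease_genes),
        size_intersection=len(inter),
        members_intersection=members,
    )
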