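"""Domain types, tab-separated readers/writers, and gene-symbol normalization.

All tabular inputs are UTF-8, tab-delimited text with a header row and '.' as
the decimal separator.  Interaction scores come in two dialects: the STRING
export convention (integer combined scores on 0-1000) and plain probabilities
on [0, 1]; the dialect is always declared explicitly, never guessed.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import DialectError, FormatError, SchemaError

ADME_PROPERTIES = ("mw", "alogp", "hdon", "hacc", "ob", "caco2", "dl", "rbn")
COMPOUND_COLUMNS = ("compound_id", "name", "herb_source") + ADME_PROPERTIES
LINK_SOURCES = ("pharmmapper", "swisstarget", "stitch", "other")
PPI_DIALECTS = ("string_0_1000", "unit_interval")
NAMESPACES = ("BP", "MF", "CC", "KEGG")


class MalformedCellWarning(UserWarning):
    """A numeric cell could not be parsed and was recorded as missing."""


class EmptyTableWarning(UserWarning):
    """A reader encountered a header-only file."""


@dataclass(frozen=True)
class CompoundRecord:
    """One compound: identity, source herb, and its eight ADME properties.

    Missing properties are ``None`` (explicitly flagged), never silently zero.
    """

    compound_id: str
    name: str
    herb_source: str
    mw: float | None = None       # molecular weight, Da
    alogp: float | None = None    # octanol-water partition estimate
    hdon: int | None = None       # H-bond donor count
    hacc: int | None = None       # H-bond acceptor count
    ob: float | None = None       # oral bioavailability, percent
    caco2: float | None = None    # Caco-2 permeability (log scale)
    dl: float | None = None       # drug-likeness index in [0, 1]
    rbn: int | None = None        # rotatable bond count

    def __post_init__(self) -> None:
        if self.mw is not None and not self.mw > 0:
            raise ValueError(f"{self.name}: mw must be positive, got {self.mw}")
        for prop in ("hdon", "hacc", "rbn"):
            v = getattr(self, prop)
            if v is not None and (v < 0 or v != int(v)):
                raise ValueError(f"{self.name}: {prop} must be a non-negative integer")
        if self.dl is not None and not 0.0 <= self.dl <= 1.0:
            raise ValueError(f"{self.name}: dl must lie in [0, 1], got {self.dl}")

    def missing_properties(self) -> tuple[str, ...]:
        return tuple(p for p in ADME_PROPERTIES if getattr(self, p) is None)


@dataclass(frozen=True)
class CompoundTargetLink:
    """A predicted compound-target association with its source-native score."""

    compound_id: str
    gene_raw: str
    source_db: str
    score: float

    def __post_init__(self) -> None:
        if self.source_db not in LINK_SOURCES:
            raise SchemaError(f"unknown target source {self.source_db!r}; "
                              f"expected one of {LINK_SOURCES}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"link score {self.score} outside [0, 1]")


@dataclass
class GeneSet:
    """A named set of normalized gene symbols with source provenance."""

    name: str
    genes: set[str]
    provenance: list[str] = field(default_factory=list)
    #: optional per-gene provenance (which sources contributed each symbol)
    gene_provenance: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def sorted(self) -> list[str]:
        return sorted(self.genes)


@dataclass
class PPINetwork:
    """Undirected scored interaction network over normalized gene symbols.

    No self-loops, no parallel edges; edge scores live in the ``score``
    edge attribute on the declared dialect's scale.
    """

    graph: nx.Graph
    dialect: str
    self_loops_dropped: int = 0
    #: nodes requested in an induction that carry no qualifying edge
    isolates: int = 0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class AnnotationTerm:
    term_id: str
    term_name: str
    namespace: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise SchemaError(f"unknown namespace {self.namespace!r}")
        if len(self.genes) < 1:
            raise SchemaError(f"term {self.term_id} has an empty gene set")


@dataclass
class AnnotationDB:
    """Annotation term database (GO/KEGG style) with an explicit background."""

    terms: list[AnnotationTerm]
    background: set[str]

    def __post_init__(self) -> None:
        for t in self.terms:
            extra = t.genes - self.background
            if extra:
                raise SchemaError(
                    f"term {t.term_id} annotates genes outside the background: "
                    f"{sorted(extra)[:5]}")


@dataclass
class SymbolMap:
    """Alias -> canonical symbol table, with ambiguous aliases flagged.

    An alias mapping to several canonical symbols is resolved to the
    lexicographically first and recorded in ``ambiguous``.
    """

    mapping: dict[str, str] = field(default_factory=dict)
    ambiguous: dict[str, tuple[str, ...]] = field(default_factory=dict)


@dataclass
class NormalizationReport:
    unmapped: list[str] = field(default_factory=list)
    ambiguous_used: dict[str, tuple[str, ...]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# symbol normalization
# ---------------------------------------------------------------------------

def read_symbol_map(path: str | Path) -> SymbolMap:
    """Read a two-column (alias, canonical) TSV into a :class:`SymbolMap`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "alias" not in cols or "canonical" not in cols:
        raise SchemaError(f"symbol map {path} needs 'alias' and 'canonical' columns")
    df.columns = cols
    candidates: dict[str, set[str]] = {}
    for alias, canonical in zip(df["alias"], df["canonical"]):
        if pd.isna(alias) or pd.isna(canonical):
            continue
        candidates.setdefault(alias.strip().upper(), set()).add(canonical.strip().upper())
    out = SymbolMap()
    for alias, canon in candidates.items():
        ordered = tuple(sorted(canon))
        out.mapping[alias] = ordered[0]
        if len(ordered) > 1:
            out.ambiguous[alias] = ordered
    return out


def normalize_symbols(
    symbols: Iterable[str],
    symbol_map: SymbolMap | Mapping[str, str] | None = None,
) -> tuple[set[str], NormalizationReport]:
    """Uppercase and canonicalize gene symbols; deduplicate.

    Unmapped symbols pass through uppercased and are listed in the report
    (they are never dropped, so downstream set sizes stay auditable).
    """
    if symbol_map is None:
        symbol_map = SymbolMap()
    elif not isinstance(symbol_map, SymbolMap):
        symbol_map = SymbolMap(mapping={k.upper(): v.upper()
                                        for k, v in symbol_map.items()})
    report = NormalizationReport()
    out: set[str] = set()
    seen_unmapped: set[str] = set()
    for sym in symbols:
        up = sym.strip().upper()
        if not up:
            continue
        if up in symbol_map.mapping:
            canonical = symbol_map.mapping[up]
            if up in symbol_map.ambiguous:
                report.ambiguous_used[up] = symbol_map.ambiguous[up]
        else:
            canonical = up
            if symbol_map.mapping and up not in symbol_map.mapping.values():
                seen_unmapped.add(up)
            elif not symbol_map.mapping:
                seen_unmapped.add(up)
        out.add(canonical)
    report.unmapped = sorted(seen_unmapped)
    return out, report


# ---------------------------------------------------------------------------
# compound tables
# ---------------------------------------------------------------------------

_INT_PROPS = {"hdon", "hacc", "rbn"}


def _parse_number(raw: object, prop: str) -> float | int | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise ValueError(raw)
    if math.isnan(value):
        return None
    return int(value) if prop in _INT_PROPS else value


def read_compound_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[CompoundRecord]:
    """Read a compound property TSV into :class:`CompoundRecord` rows.

    ``column_map`` maps the canonical field names to the file's column
    headers; by default the canonical names themselves are expected.
    Malformed numeric cells are recorded as missing, each with a
    :class:`MalformedCellWarning`.
    """
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep="\t", dtype=str)
    resolved = {f: column_map.get(f, f) for f in COMPOUND_COLUMNS}
    absent = [src for src in resolved.values() if src not in df.columns]
    if absent:
        raise SchemaError(f"{path}: missing mandatory column(s) {absent}")
    if df.empty:
        warnings.warn(f"{path}: header-only compound table", EmptyTableWarning)
        return []
    records: list[CompoundRecord] = []
    for _, row in df.iterrows():
        kwargs: dict[str, object] = {
            "compound_id": str(row[resolved["compound_id"]]).strip(),
            "name": str(row[resolved["name"]]).strip(),
            "herb_source": str(row[resolved["herb_source"]]).strip(),
        }
        for prop in ADME_PROPERTIES:
            raw = row[resolved[prop]]
            try:
                kwargs[prop] = _parse_number(raw, prop)
            except ValueError:
                warnings.warn(
                    f"{path}: malformed {prop} value {raw!r} for compound "
                    f"{kwargs['compound_id']}; recorded as missing",
                    MalformedCellWarning)
                kwargs[prop] = None
        records.append(CompoundRecord(**kwargs))  # type: ignore[arg-type]
    return records


def write_compound_table(records: Sequence[CompoundRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({c: getattr(r, c) for c in COMPOUND_COLUMNS})
    pd.DataFrame(rows, columns=list(COMPOUND_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# target links and gene lists
# ---------------------------------------------------------------------------

def read_target_links(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[CompoundTargetLink]:
    """Read a compound->target link TSV (compound_id, gene, source_db, score)."""
    column_map = dict(column_map or {})
    fields = ("compound_id", "gene_raw", "source_db", "score")
    df = pd.read_csv(path, sep="\t", dtype=str)
    resolved = {f: column_map.get(f, f) for f in fields}
    absent = [src for src in resolved.values() if src not in df.columns]
    if absent:
        raise SchemaError(f"{path}: missing mandatory column(s) {absent}")
    links = []
    for _, row in df.iterrows():
        links.append(CompoundTargetLink(
            compound_id=str(row[resolved["compound_id"]]).strip(),
            gene_raw=str(row[resolved["gene_raw"]]).strip(),
            source_db=str(row[resolved["source_db"]]).strip().lower(),
            score=float(row[resolved["score"]]),
        ))
    return links


def write_target_links(links: Sequence[CompoundTargetLink], path: str | Path) -> None:
    pd.DataFrame(
        [{"compound_id": l.compound_id, "gene_raw": l.gene_raw,
          "source_db": l.source_db, "score": l.score} for l in links]
    ).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line (or single-column TSV) gene list."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.strip().split("\t")[0].strip()
            if token and token.lower() not in {"gene", "symbol", "name"}:
                out.append(token)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# PPI edge lists
# ---------------------------------------------------------------------------

def _score_bounds(dialect: str) -> tuple[float, float]:
    if dialect == "string_0_1000":
        return 0.0, 1000.0
    if dialect == "unit_interval":
        return 0.0, 1.0
    raise DialectError(f"unknown PPI score dialect {dialect!r}; "
                       f"expected one of {PPI_DIALECTS}")


def read_ppi_edges(
    path: str | Path,
    dialect: str = "string_0_1000",
    min_score: float = 700.0,
) -> PPINetwork:
    """Read a STRING-style edge list keeping edges strictly above ``min_score``.

    Duplicate unordered pairs collapse to the maximum score; self-loops are
    dropped and counted.  A score outside the declared dialect's range is a
    fatal :class:`DialectError`.
    """
    lo, hi = _score_bounds(dialect)
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    cols = list(df.columns)
    if len(cols) < 3:
        raise SchemaError(f"{path}: PPI edge list needs two gene columns + a score")
    g = nx.Graph()
    loops = 0
    for a, b, s in zip(df[cols[0]], df[cols[1]], df[cols[2]]):
        score = float(s)
        if not lo <= score <= hi:
            raise DialectError(
                f"{path}: score {score} outside the {dialect} scale [{lo}, {hi}]")
        ga, gb = str(a).strip().upper(), str(b).strip().upper()
        if ga == gb:
            loops += 1
            continue
        if score > min_score:
            if g.has_edge(ga, gb):
                g[ga][gb]["score"] = max(g[ga][gb]["score"], score)
            else:
                g.add_edge(ga, gb, score=score)
    return PPINetwork(graph=g, dialect=dialect, self_loops_dropped=loops)


def write_ppi_edges(network: PPINetwork, path: str | Path) -> None:
    rows = [{"gene_a": a, "gene_b": b, "combined_score": d["score"]}
            for a, b, d in network.graph.edges(data=True)]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "combined_score"]) \
        .to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("sif", "graphml", "tsv")


def _node_attr_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".nodes.tsv")


def write_network(graph: nx.Graph, path: str | Path, fmt: str = "sif") -> None:
    """Export a graph for Cytoscape-class viewers.

    ``sif`` and ``tsv`` exports write a sibling ``*.nodes.tsv`` attribute
    table so isolated nodes and node attributes survive the round trip;
    ``graphml`` keeps everything in one file.
    """
    path = Path(path)
    if fmt not in NETWORK_FORMATS:
        raise FormatError(f"unknown network format {fmt!r}; expected {NETWORK_FORMATS}")
    if fmt == "graphml":
        nx.write_graphml(graph, path)
        return
    with open(path, "w", encoding="utf-8") as fh:
        if fmt == "tsv":
            fh.write("source\tinteraction\ttarget\n")
        for a, b in sorted(graph.edges()):
            rel = graph[a][b].get("interaction", "pp")
            fh.write(f"{a}\t{rel}\t{b}\n")
    attrs = sorted({k for _, d in graph.nodes(data=True) for k in d})
    with open(_node_attr_path(path), "w", encoding="utf-8") as fh:
        fh.write("\t".join(["node"] + attrs) + "\n")
        for n in sorted(graph.nodes()):
            d = graph.nodes[n]
            fh.write("\t".join([str(n)] + [str(d.get(k, "")) for k in attrs]) + "\n")


def read_network(path: str | Path, fmt: str = "sif") -> nx.Graph:
    """Re-read a :func:`write_network` export (round-trip partner)."""
    path = Path(path)
    if fmt not in NETWORK_FORMATS:
        raise FormatError(f"unknown network format {fmt!r}; expected {NETWORK_FORMATS}")
    if fmt == "graphml":
        return nx.read_graphml(path)
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if fmt == "tsv":
        lines = lines[1:]
    for line in lines:
        if not line.strip():
            continue
        a, rel, b = line.split("\t")
        g.add_edge(a, b, interaction=rel)
    nodes_file = _node_attr_path(path)
    if nodes_file.exists():
        with open(nodes_file, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                node = parts[0]
                g.add_node(node)
                for key, val in zip(header[1:], parts[1:]):
                    if val != "":
                        g.nodes[node][key] = val
    return g


# ---------------------------------------------------------------------------
# GMT annotation databases
# ---------------------------------------------------------------------------

def read_gmt(
    path: str | Path,
    namespace: str = "KEGG",
    background: Iterable[str] | None = None,
) -> AnnotationDB:
    """Read a GMT file (term_id <tab> term_name <tab> gene ...).

    The background defaults to the union of all annotated genes; pass an
    explicit universe to widen it.
    """
    terms = []
    genes_seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0].strip():
                continue
            genes = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
            terms.append(AnnotationTerm(parts[0].strip(), parts[1].strip(),
                                        namespace, genes))
            genes_seen |= genes
    bg = set(g.upper() for g in background) if background is not None else genes_seen
    return AnnotationDB(terms=terms, background=bg)


def write_gmt(db: AnnotationDB, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in db.terms:
            fh.write("\t".join([t.term_id, t.term_name] + sorted(t.genes)) + "\n")
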