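"""Over-representation analysis with hypergeometric tails and BH adjustment.

For a query gene set of size n drawn against a background of N annotated
genes, a term annotating K genes with k of them in the query is scored by
the upper-tail hypergeometric probability P(X >= k).  Raw p-values are
adjusted per namespace with the Benjamini-Hochberg step-up procedure, and
terms with adjusted p strictly below alpha are reported, together with the
"% associated genes" statistic 100*k/K used on bubble-chart x-axes.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import StageError
from .io import AnnotationDB

DEFAULT_ALPHA = 0.001


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    namespace: str
    hit_count: int
    term_size: int
    query_size: int
    background_size: int
    p_raw: float
    p_adj: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_raw <= 1.0:
            raise ValueError(f"{self.term_id}: p_raw={self.p_raw} outside (0, 1]")
        if self.p_adj < self.p_raw - 1e-15:
            raise ValueError(f"{self.term_id}: p_adj below p_raw")
        if self.hit_count > min(self.term_size, self.query_size):
            raise ValueError(f"{self.term_id}: impossible hit count")

    @property
    def pct_associated(self) -> float:
        """100 x (query hits in the term) / (term size)."""
        return 100.0 * self.hit_count / self.term_size


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    k = hits in the query, n = query size, K = term size, N = background.
    Evaluated through the survival function (log-space internals), exact at
    k = 0 where the tail is the whole sample space.
    """
    if not (0 <= k <= min(n, K)) or n > N or K > N or min(n, K, N) < 0:
        raise StageError(
            f"inconsistent counts: k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    adj_i = min over j >= i (sorted) of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise StageError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_gene_set(
    query: Iterable[str],
    annotation_db: AnnotationDB,
    background: Iterable[str] | None = None,
    alpha: float | None = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """Test every term with at least one query hit; BH per namespace.

    The background defaults to all genes annotated in the database; an
    explicit universe can be passed instead.  Only results with adjusted
    p strictly below ``alpha`` are returned, sorted by adjusted p then
    term id; ``alpha=None`` disables the filter and returns every tested
    term.  Query genes outside the background are ignored for counting
    (they cannot be drawn from the urn).
    """
    if not annotation_db.terms:
        raise StageError("annotation database has no terms")
    if alpha is not None and not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    bg = set(background) if background is not None else set(annotation_db.background)
    q = {g.strip().upper() for g in query} & bg
    n, N = len(q), len(bg)

    tested: list[tuple] = []  # (namespace, term, k, p_raw)
    for term in annotation_db.terms:
        genes = term.genes & bg
        k = len(q & genes)
        if k >= 1:
            tested.append((term, k, hypergeom_pvalue(k, n, len(genes), N)))

    results: list[EnrichmentResult] = []
    for namespace in sorted({t.namespace for t, _, _ in tested}):
        group = [(t, k, p) for t, k, p in tested if t.namespace == namespace]
        adj = bh_adjust([p for _, _, p in group])
        for (term, k, p_raw), p_adj in zip(group, adj):
            results.append(EnrichmentResult(
                term_id=term.term_id, term_name=term.term_name,
                namespace=namespace, hit_count=k,
                term_size=len(term.genes & bg), query_size=n,
                background_size=N, p_raw=p_raw, p_adj=float(p_adj)))
    if alpha is not None:
        results = [r for r in results if r.p_adj < alpha]
    results.sort(key=lambda r: (r.p_adj, r.term_id))
    return results


def bubble_data(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Plot-ready table: term, % associated genes, hit count, -log10(p_adj)."""
    if not results:
        raise StageError("no enrichment results to plot")
    rows = [{
        "term_name": r.term_name,
        "pct_associated": r.pct_associated,
        "hit_count": r.hit_count,
        "neg_log10_p_adj": float(-np.log10(r.p_adj)),
    } for r in sorted(results, key=lambda r: (r.p_adj, r.term_id))]
    return pd.DataFrame(rows, columns=["term_name", "pct_associated",
                                       "hit_count", "neg_log10_p_adj"])


def write_enrichment_table(results: Sequence[EnrichmentResult],
                           path: str | Path) -> None:
    columns = ["term_id", "term_name", "namespace", "p_raw", "p_adj_bh",
               "gene_count", "term_size", "pct_associated"]
    pd.DataFrame([{
        "term_id": r.term_id, "term_name": r.term_name, "namespace": r.namespace,
        "p_raw": r.p_raw, "p_adj_bh": r.p_adj, "gene_count": r.hit_count,
        "term_size": r.term_size, "pct_associated": r.pct_associated,
    } for r in results], columns=columns).to_csv(path, sep="\t", index=False)
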