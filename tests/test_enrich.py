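import numpy as np
import pytest

from _oracles import exact_hypergeom_tail, textbook_bh
from herbnet.enrich import (bh_adjust, bubble_data, enrich_gene_set,
                            hypergeom_pvalue)
from herbnet.errors import StageError
from herbnet.io import AnnotationDB, AnnotationTerm
from herbnet.simulate import SyntheticScenario, gen_annotation_with_planted_terms


# ---------------------------------------------------------------------------
# hypergeometric tail
# ---------------------------------------------------------------------------

def test_zero_hits_gives_probability_one_exactly():
    assert hypergeom_pvalue(0, 10, 5, 100) == 1.0


def test_three_of_three_draws_matches_enumeration():
    # C(5,3)/C(10,3) = 10/120
    assert hypergeom_pvalue(3, 3, 5, 10) == pytest.approx(10 / 120, abs=1e-12)


def test_matches_exact_enumeration_on_random_instances():
    rng = np.random.default_rng(20)
    for _ in range(100):
        N = int(rng.integers(2, 40))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(0, N + 1))
        k = int(rng.integers(0, min(n, K) + 1))
        assert hypergeom_pvalue(k, n, K, N) == pytest.approx(
            exact_hypergeom_tail(k, n, K, N), rel=1e-10, abs=1e-12)


def test_matches_monte_carlo_sampling_oracle():
    rng = np.random.default_rng(22)
    draws = 10 ** 5
    for N, K, n, k in [(30, 10, 8, 4), (50, 25, 10, 7), (20, 5, 10, 2)]:
        urn = np.array([1] * K + [0] * (N - K))
        hits = np.array([urn[rng.permutation(N)[:n]].sum()
                         for _ in range(draws)])
        est = float((hits >= k).mean())
        se = max(np.sqrt(est * (1 - est) / draws), 1e-4)
        assert abs(hypergeom_pvalue(k, n, K, N) - est) < 3 * se


def test_non_increasing_in_hits():
    ps = [hypergeom_pvalue(k, 12, 15, 60) for k in range(13)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_inconsistent_counts_are_fatal():
    with pytest.raises(StageError):
        hypergeom_pvalue(5, 3, 10, 20)  # k > n
    with pytest.raises(StageError):
        hypergeom_pvalue(1, 30, 10, 20)  # n > N


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def test_singleton_unchanged():
    assert bh_adjust([0.042]) == pytest.approx([0.042])


def test_equal_pvalues_stay_at_their_value():
    assert bh_adjust([0.03] * 5) == pytest.approx([0.03] * 5)


def test_hand_evaluated_step_up():
    assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])


def test_matches_textbook_step_up_and_order_invariance():
    rng = np.random.default_rng(23)
    p = rng.uniform(1e-6, 1, 40)
    adj = bh_adjust(p)
    assert adj == pytest.approx(textbook_bh(p.tolist()))
    perm = rng.permutation(40)
    assert bh_adjust(p[perm]) == pytest.approx(adj[perm])
    assert np.all(adj >= p) and np.all(adj <= 1.0)


def test_out_of_range_pvalues_are_fatal():
    with pytest.raises(StageError):
        bh_adjust([0.0, 0.5])
    with pytest.raises(StageError):
        bh_adjust([1.5])


# ---------------------------------------------------------------------------
# enrichment of a gene set
# ---------------------------------------------------------------------------

def _db():
    bg = {f"G{i}" for i in range(100)}
    return AnnotationDB(terms=[
        AnnotationTerm("T1", "whole background", "KEGG", frozenset(bg)),
        AnnotationTerm("T2", "small", "KEGG", frozenset({"G0", "G1", "G2"})),
    ], background=bg)


def test_term_equal_to_background_has_p_one():
    results = enrich_gene_set(["G0", "G1"], _db(), alpha=None)
    whole = next(r for r in results if r.term_id == "T1")
    assert whole.p_raw == 1.0


def test_query_disjoint_from_all_terms_gives_empty_results():
    bg = {f"G{i}" for i in range(50)}
    db = AnnotationDB(terms=[AnnotationTerm("T", "t", "BP",
                                            frozenset({"G1", "G2"}))],
                      background=bg)
    assert enrich_gene_set(["G40", "G41"], db, alpha=0.5) == []


def test_empty_annotation_is_fatal():
    with pytest.raises(StageError):
        enrich_gene_set(["G1"], AnnotationDB(terms=[], background={"G1"}))


def test_planted_term_ranks_first():
    scenario = SyntheticScenario(seed=31)
    rng = np.random.default_rng(31)
    query = [f"G{i:04d}" for i in rng.choice(3000, 200, replace=False)]
    db, manifest = gen_annotation_with_planted_terms(scenario, query)
    results = enrich_gene_set(query, db, alpha=0.999999)
    assert results[0].term_id in manifest["planted_terms"]


def test_alpha_filter_is_strict_on_adjusted_p():
    scenario = SyntheticScenario(seed=32)
    rng = np.random.default_rng(32)
    query = [f"G{i:04d}" for i in rng.choice(3000, 200, replace=False)]
    db, _ = gen_annotation_with_planted_terms(scenario, query)
    results = enrich_gene_set(query, db, alpha=0.001)
    assert all(r.p_adj < 0.001 for r in results)
    assert all(r.p_adj >= r.p_raw for r in results)


def test_bubble_table_values_and_roundtrip():
    scenario = SyntheticScenario(seed=33)
    rng = np.random.default_rng(33)
    query = [f"G{i:04d}" for i in rng.choice(3000, 200, replace=False)]
    db, _ = gen_annotation_with_planted_terms(scenario, query)
    results = enrich_gene_set(query, db, alpha=0.999999)
    table = bubble_data(results)
    r0 = results[0]
    assert table.iloc[0]["pct_associated"] == pytest.approx(
        100 * r0.hit_count / r0.term_size)
    assert table.iloc[0]["neg_log10_p_adj"] == pytest.approx(-np.log10(r0.p_adj))
    # deterministic ordering: identical result set -> identical table
    assert bubble_data(list(reversed(results))).equals(table)


def test_bubble_closed_forms():
    from herbnet.enrich import EnrichmentResult
    r = EnrichmentResult("T", "t", "KEGG", hit_count=5, term_size=20,
                         query_size=30, background_size=100,
                         p_raw=0.001, p_adj=0.001)
    table = bubble_data([r])
    assert table.iloc[0]["pct_associated"] == 25.0
    assert table.iloc[0]["neg_log10_p_adj"] == pytest.approx(3.0)
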