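# Methods

## Pipeline model

The pipeline is a fixed chain of pure stages; each consumes files or
in-memory objects and emits audit tables:

`screen → aggregate → intersect → induce → centralities → hubs → hct → enrich`

### ADME oral-activity screen

A compound passes when all eight criteria hold:

| property | criterion |
|---|---|
| molecular weight | `< 500` |
| AlogP | `< 5` |
| H-bond donors | `< 5` |
| H-bond acceptors | `< 10` |
| oral bioavailability (%) | `>= 30` |
| drug-likeness | `>= 0.18` |
| Caco-2 permeability | `> -0.4` |
| rotatable bonds | `<= 10` |

The Lipinski and Caco-2 comparisons are strict; OB, DL and RBN are
inclusive (the packaged table contains compounds at exactly DL = 0.18
that were accepted, which fixes the convention). Missing properties are
governed by a policy (`fail` by default, `pass` or `error` optional).

### Target aggregation and the Venn core

Compound→target links carry a source and a confidence in [0, 1]; a link
qualifies when its score is **strictly greater than 0.7** (per-source
thresholds can be overridden). Qualifying targets are unioned across
compounds with per-gene provenance retained. Disease genes are the union
of the supplied repository lists. The analysis set is the intersection
of the formula target union and the disease union.

### PPI topology

Edge lists are read in an explicit dialect — `string_0_1000` (combined
scores 0–1000) or `unit_interval` — keeping edges **strictly above** the
minimum score (default 700), dropping self-loops and collapsing
duplicates to the maximum score. The subgraph induced on the analysis
set keeps isolated genes (their count is reported).

Centralities:

- **degree** — `simple` counts each incident edge once; `doubled`
  counts each undirected edge twice (the convention of the network
  viewer behind the packaged tables, where every printed degree is
  even). Default for exported tables: `doubled`.
- **betweenness** — shortest-path betweenness normalised by
  `(n-1)(n-2)/2` (networkx `normalized=True`).
- **closeness** — within-component closeness `(k-1)/Σd` without the
  Wasserman–Faust size correction (networkx `wf_improved=False`);
  isolates score 0.

**Hub selection**: genes whose degree, betweenness and closeness all
exceed the respective medians of the induced network (numpy median:
mean-of-middle-two for even counts). Default policy `strict` (`>`);
`inclusive` (`>=`) is available. With the packaged 79-gene table and its
recorded cutoffs both policies return all 79 genes, so the published
convention is not decidable from the tables alone — it is a flag.

### Herb–compound–target network

Nodes are typed (disease, formula, herb, compound, target); compound →
target edges are kept only for targets in the analysis core, and the
disease node is wired to every core target. Compound degree is counted
over target edges only by default (`all_edges` adds the herb
attachment). Main compounds are those with degree **strictly above** the
median compound degree; compounds exactly at the median are flagged but
not selected. Subsetting to chosen compounds (e.g. experimentally
validated ones) removes the others with their exclusive edges and flags
targets left uncovered.

### Enrichment

For a query of size *n* against a term with *K* annotated background
genes out of *N*, the p-value is the hypergeometric upper tail
`P(X >= k)`, computed via the survival function in log space
(`scipy.stats.hypergeom.sf(k-1, N, K, n)`); `k = 0` gives exactly 1.
Only terms with at least one query hit are tested. Benjamini–Hochberg
adjustment (statsmodels `fdr_bh`) is applied per namespace, and results
with **adjusted p strictly below 0.001** are retained (configurable).
`pct_associated = 100·k/K` supports bubble-plot exports.

## Synthetic data with planted ground truth

All generators are pure functions of a `SyntheticScenario`; every random
stream is `numpy.random.default_rng([seed, tag])` with a fixed
per-generator tag, so bundles are byte-identical across runs.

- **Compound table** — exactly `round(n·pass_fraction)` compounds pass;
  each planted failure violates exactly one criterion, so the screen can
  be checked verdict-by-verdict.
- **PPI graph** — a core–periphery graph: planted hubs connect to other
  nodes with probability `p_within_hub_core = 0.5` against a background
  of `p_background = 0.02`. Planting with `p_within <= p_background` is
  rejected as unidentifiable.
- **Targets and disease lists** — the overlap between the formula
  target union (290) and the disease union (2,400 genes over a 3,000
  gene universe) is planted exactly (239 by default); qualifying links
  get scores above the 0.7 threshold, noise links at or below it.
- **Annotation** — terms sample genes uniformly except planted terms,
  which weight query genes at odds 20. Planted terms have a fixed size
  (60) rather than a sampled one: a small term cannot reach significance
  at any odds, so fixing the size keeps the planted signal identifiable.
  Odds ≤ 1 planting is rejected.

Scope: the generators model list sizes, score thresholds and topology
only. They do not model chemistry (property values are sampled uniformly
inside pass/fail ranges), real PPI degree distributions, or correlated
annotation terms.

## Numerical choices

- Medians via `numpy.median`; hypergeometric tails via `scipy.stats`
  (log-space, no explicit factorials); BH via `statsmodels`.
- Each of these is cross-checked in the test suite against an
  independent oracle: exhaustive shortest-path enumeration for
  betweenness/closeness, `math.comb` enumeration for the hypergeometric
  tail, and a textbook step-up loop for BH.
- Floats round-trip through TSV exports (`float_precision="round_trip"`
  on read).
- Output tables are sorted deterministically (centrality: degree desc,
  betweenness desc, gene; enrichment: adjusted p, term id).

## Limitations

- The hypergeometric test is discrete, hence conservative: its exact
  attainable rejection level at nominal 0.05 lies below 0.05 and depends
  on (N, K, n). The calibration test compares the empirical rejection
  rate against the exact attainable level, not the nominal one.
- The median hub rule keeps roughly half of the nodes of a typical
  network; it is a coarse filter, not a classifier. Recovery of planted
  hubs is therefore assessed as containment plus agreement of the
  equally sized top slice of the ranking.
- Closeness on disconnected graphs is a within-component quantity;
  comparing values across components of different sizes is not
  meaningful.
- The packaged tables are printed summaries: re-selection and re-ranking
  from them is exact, but upstream quantities that depended on external
  database releases (full interaction lists, full annotation databases)
  are not desk-reproducible and are covered by the synthetic generators
  instead.
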