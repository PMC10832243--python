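# herbnet

Network pharmacology of herbal formulas: from ADME screening of candidate
compounds to hub-gene selection and pathway enrichment, in one reproducible
pipeline.

## The scientific problem

Herbal formulas act through many compounds hitting many protein targets at
once, so their mechanism cannot be read off a single dose–response curve.
Network pharmacology approaches the question combinatorially:

1. **ADME screen** — keep only candidate compounds that are plausibly
   orally active, using eight published cutoffs (Lipinski's rule of five
   plus oral bioavailability, drug-likeness, Caco-2 permeability and
   rotatable-bond count).
2. **Target aggregation** — pool per-source compound→target predictions,
   keeping links with confidence strictly above 0.7, and union them into
   the formula's target set.
3. **Disease intersection** — union disease gene lists from several
   repositories and intersect them with the formula targets (the Venn
   core).
4. **PPI topology** — induce the protein–protein interaction subgraph on
   the core genes from a STRING-style edge list and compute degree,
   betweenness and closeness centralities.
5. **Hub selection** — keep genes whose three centralities all exceed the
   network medians (strict `>` by default).
6. **Herb–compound–target network** — wire formula → herbs → compounds →
   core targets → disease, rank compounds by target degree, and select
   main compounds strictly above the median degree.
7. **Enrichment** — hypergeometric over-representation of the hub genes
   against GO/KEGG-style annotations, Benjamini–Hochberg adjusted, with a
   strict `p_adj < 0.001` significance filter.

The package ships the printed summary tables of the SH003 formula study
(three herbs: *Astragalus membranaceus*, *Angelica gigas*, *Trichosanthes
kirilowii*; disease context NSCLC) as text fixtures, and a synthetic-data
module that generates full input bundles with **planted ground truth**
(known ADME verdicts, a known Venn overlap, planted network hubs, planted
enriched terms), so every stage can be tested against known answers.

## Worked example

Re-select hub genes and main compounds from the packaged SH003 tables
(`examples/hub_genes_from_published_tables.py`):

```python
from herbnet.datasets import (SH003_MEDIANS, load_sh003_compound_degrees,
                              load_sh003_hub_table)
from herbnet.hct import rank_degree_values
from herbnet.ppi import select_hub_genes

selection = select_hub_genes(load_sh003_hub_table(), SH003_MEDIANS, "strict")
rank = rank_degree_values(load_sh003_compound_degrees())
```

Output of the example script:

```
hub table rows: 79; re-selected hubs: 79
top five by degree: TP53, JUN, AKT1, MAPK3, STAT3
hub table after restricting to the four validated compounds: 64 genes

compound degree median: 10.0
main compounds (degree strictly above the median): 8
  Luteolin: 48
  Baicalein: 34
  Kaempferol: 31
  Wogonin: 21
  Hesperetin: 15
  Isorhamnetin: 14
  Hispidulin: 12
  Chrysoeriol: 11
at the median (flagged, not selected): 7-O-Methylluteolin, Calycosin, Diosmetin
```

Run the whole pipeline on synthetic data with planted ground truth
(`examples/synthetic_pipeline_end_to_end.py`):

```
pipeline counts:
  candidates: 100
  passing_compounds: 20
  ...
  venn_intersection: 239
  ppi_nodes: 239
  hub_genes: 71
  selected_compounds: 8
  significant_terms: 1

planted hubs all selected: True
venn intersection matches planted overlap: True
```

The same pipeline is available from the shell:

```sh
herbnet simulate --seed 5 --outdir bundle/
herbnet run-all config.yaml
herbnet screen bundle/compounds.tsv --out passing.tsv
```

## Reproduction

All tests, including the acceptance suite:

```sh
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

Headline quantities, recomputed from the packaged tables and a
seed-derived synthetic run, written as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Everything is deterministic given `--seed`; re-running a pipeline on the
same inputs produces byte-identical outputs.

## Repository layout

- `src/herbnet/` — the library: `io`, `adme`, `targets`, `ppi`, `hct`,
  `enrich`, `simulate`, `pipeline`, `datasets`, `cli`.
- `src/herbnet/data/` — packaged SH003 text fixtures (compound table,
  hub tables, compound degrees).
- `examples/` — short narrative scripts.
- `tests/` — unit, property and acceptance tests with independent
  brute-force oracles (`tests/_oracles.py`).
- `docs/methods.md` — model, conventions and numerical choices.
- `scripts/acceptance.py` — recompute the headline quantities.
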