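"""Re-select hub genes from the packaged SH003 centrality tables.

Hub genes are those whose degree, betweenness and closeness centralities
all exceed the medians of the induced interaction network.  The packaged
table lists the 79 published hubs with the cutoffs they were selected
under; re-running the selection at those cutoffs must return the whole
table.  Compound ranking by degree uses the same median rule.
"""

from herbnet.datasets import (SH003_MEDIANS, load_sh003_compound_degrees,
                              load_sh003_hub_table,
                              load_sh003_validated_hub_table)
from herbnet.hct import rank_degree_values
from herbnet.ppi import select_hub_genes

table = load_sh003_hub_table()
selection = select_hub_genes(table, SH003_MEDIANS, "strict")
print(f"hub table rows: {len(table)}; re-selected hubs: {len(selection.hubs)}")
print("top five by degree:",
      ", ".join(r.gene for r in selection.hubs[:5]))

validated = load_sh003_validated_hub_table()
print(f"hub table after restricting to the four validated compounds: "
      f"{len(validated)} genes")

rank = rank_degree_values(load_sh003_compound_degrees())
print(f"\ncompound degree median: {rank.median_degree}")
print(f"main compounds (degree strictly above the median): "
      f"{len(rank.selected)}")
for compound, degree in rank.ranking[:len(rank.selected)]:
    print(f"  {compound}: {degree}")
print("at the median (flagged, not selected):", ", ".join(rank.at_median))
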