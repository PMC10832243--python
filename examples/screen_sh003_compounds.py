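"""Screen the packaged SH003 compound table for oral activity.

SH003 is a three-herb formula (Astragalus membranaceus, Angelica gigas,
Trichosanthes kirilowii).  Each candidate compound carries eight ADME
properties; a compound is kept only if it satisfies all eight published
cutoffs (Lipinski's rule of five plus oral bioavailability,
drug-likeness, Caco-2 permeability and rotatable-bond count).
"""

from herbnet.adme import default_criteria, screen_compounds, verdict_table
from herbnet.datasets import load_sh003_compounds

compounds = load_sh003_compounds()
result = screen_compounds(compounds)

print(f"candidates: {len(compounds)}")
print(f"orally active: {len(result.passing)}")
for herb, n in sorted(result.per_herb_counts.items()):
    print(f"  {herb}: {n}")

print("\ncriteria applied:")
for prop, criterion in default_criteria().items():
    print(f"  {prop} {criterion.op} {criterion.threshold}")

# the verdict table records, per compound, which criteria held
table = verdict_table(result)
print(f"\nverdict table: {len(table)} compound x criterion rows")
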