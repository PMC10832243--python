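"""Bundled reference tables for the SH003 / non-small-cell-lung-cancer case study.

SH003 is a three-herb formula (Astragalus membranaceus AM, Angelica gigas AG,
Trichosanthes kirilowii TK).  The tables shipped here are the published
desk-level results of its network-pharmacology analysis against NSCLC:

- the 20 orally active compounds with their eight ADME properties,
- the 79-gene hub centrality table of the full compound set,
- the 64-gene hub table of the four assay-validated compounds,
- the compound degree ranking in the herb-compound-target network.

They serve as worked examples and as regression fixtures for the screening,
hub-selection and ranking rules.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import CompoundRecord, read_compound_table
from .ppi import CentralityRecord


def _path(name: str):
    return resources.files("herbnet.data") / name


def load_sh003_compounds() -> list[CompoundRecord]:
    """The 20 orally active SH003 compounds (15 AM, 1 AG, 4 TK)."""
    with resources.as_file(_path("sh003_active_compounds.tsv")) as p:
        return read_compound_table(p)


def _load_hub_table(name: str) -> list[CentralityRecord]:
    with resources.as_file(_path(name)) as p:
        df = pd.read_csv(p, sep="\t")
    return [CentralityRecord(gene=r.gene, degree=int(r.degree),
                             betweenness=float(r.betweenness),
                             closeness=float(r.closeness))
            for r in df.itertuples(index=False)]


def load_sh003_hub_table() -> list[CentralityRecord]:
    """The 79 hub genes of the full 20-compound analysis (degree in the
    doubled viewer convention)."""
    return _load_hub_table("sh003_hub_table_full.tsv")


def load_sh003_validated_hub_table() -> list[CentralityRecord]:
    """The 64 hub genes of the four assay-validated compounds."""
    return _load_hub_table("sh003_hub_table_validated.tsv")


def load_sh003_compound_degrees() -> dict[str, int]:
    """Compound degrees in the herb-compound-target network (20 compounds)."""
    with resources.as_file(_path("sh003_compound_degrees.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return dict(zip(df["compound"], df["degree"].astype(int)))


#: the published median cutoffs of the 239-node full-run centrality table
SH003_MEDIANS = (20.0, 0.00156, 0.38889)

#: the four compounds confirmed in the extract by LC-MS
SH003_VALIDATED_COMPOUNDS = ("Hispidulin", "Luteolin", "Baicalein", "Chrysoeriol")
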