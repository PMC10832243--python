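"""Oral-activity screening of herbal compounds by eight ADME criteria.

A compound is declared orally active when it satisfies Lipinski's rule of
five (MW < 500 Da, ALogP < 5, Hdon < 5, Hacc < 10) together with four
pharmacokinetic cutoffs: oral bioavailability OB >= 30 %, drug-likeness
DL >= 0.18, Caco-2 permeability > -0.4, and rotatable bond count RBN <= 10.
Operator strictness follows the published criteria verbatim: the Lipinski
and Caco-2 bounds are strict, the OB/DL/RBN bounds are inclusive (drug-like
reference tables accept compounds sitting exactly at DL = 0.18).
"""
from __future__ import annotations

import operator
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .errors import SchemaError
from .io import ADME_PROPERTIES, CompoundRecord

_OPS: Mapping[str, Callable[[float, float], bool]] = {
    "<": operator.lt,
    "<=": operator.le,
    ">": operator.gt,
    ">=": operator.ge,
}

MISSING_POLICIES = ("fail", "pass", "error")


@dataclass(frozen=True)
class Criterion:
    """A single threshold test, e.g. ``Criterion('<', 500.0)`` for MW."""

    op: str
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"operator must be one of {sorted(_OPS)}, got {self.op!r}")

    def test(self, value: float) -> bool:
        return _OPS[self.op](value, self.threshold)

    def __str__(self) -> str:
        return f"{self.op} {self.threshold:g}"


def default_criteria() -> dict[str, Criterion]:
    """The eight oral-activity cutoffs (Lipinski + OB/DL/Caco-2/RBN)."""
    return {
        "mw": Criterion("<", 500.0),
        "alogp": Criterion("<", 5.0),
        "hdon": Criterion("<", 5.0),
        "hacc": Criterion("<", 10.0),
        "ob": Criterion(">=", 30.0),
        "dl": Criterion(">=", 0.18),
        "caco2": Criterion(">", -0.4),
        "rbn": Criterion("<=", 10.0),
    }


@dataclass(frozen=True)
class AdmeCriteria:
    """The full eight-property screen plus the policy for missing values.

    ``missing_policy``: 'fail' treats an absent property as a failed
    criterion (a compound lacking data cannot be declared orally active),
    'pass' waives the criterion, 'error' raises.
    """

    criteria: Mapping[str, Criterion] = field(default_factory=default_criteria)
    missing_policy: str = "fail"

    def __post_init__(self) -> None:
        missing = set(ADME_PROPERTIES) - set(self.criteria)
        if missing:
            raise SchemaError(f"criteria must cover all eight properties; "
                              f"missing {sorted(missing)}")
        if self.missing_policy not in MISSING_POLICIES:
            raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")


@dataclass
class ScreenResult:
    passing: list[CompoundRecord]
    per_compound_verdicts: dict[str, dict[str, bool]]
    per_herb_counts: dict[str, int]


def is_orally_active(
    record: CompoundRecord,
    criteria: AdmeCriteria | None = None,
) -> tuple[bool, dict[str, bool]]:
    """Test one compound; returns the conjunction and per-criterion verdicts."""
    criteria = criteria or AdmeCriteria()
    verdicts: dict[str, bool] = {}
    for prop in ADME_PROPERTIES:
        value = getattr(record, prop)
        if value is None:
            if criteria.missing_policy == "error":
                raise SchemaError(
                    f"compound {record.compound_id} ({record.name}) is missing "
                    f"property {prop!r}")
            verdicts[prop] = criteria.missing_policy == "pass"
        else:
            verdicts[prop] = criteria.criteria[prop].test(float(value))
    return all(verdicts.values()), verdicts


def screen_compounds(
    records: Iterable[CompoundRecord],
    criteria: AdmeCriteria | None = None,
) -> ScreenResult:
    """Screen a compound table; deterministic and input-order independent."""
    criteria = criteria or AdmeCriteria()
    passing: list[CompoundRecord] = []
    verdict_map: dict[str, dict[str, bool]] = {}
    herb_counts: dict[str, int] = {}
    for rec in sorted(records, key=lambda r: (r.herb_source, r.compound_id, r.name)):
        ok, verdicts = is_orally_active(rec, criteria)
        verdict_map[rec.compound_id] = verdicts
        if ok:
            passing.append(rec)
            herb_counts[rec.herb_source] = herb_counts.get(rec.herb_source, 0) + 1
    return ScreenResult(passing=passing,
                        per_compound_verdicts=verdict_map,
                        per_herb_counts=herb_counts)


def verdict_table(result: ScreenResult) -> list[dict[str, object]]:
    """Flatten the audit verdicts to one row per compound x criterion."""
    rows = []
    for cid, verdicts in sorted(result.per_compound_verdicts.items()):
        for prop, ok in verdicts.items():
            rows.append({"compound_id": cid, "criterion": prop, "passed": ok})
    return rows


def write_verdict_table(result: ScreenResult, path) -> None:
    import pandas as pd

    pd.DataFrame(verdict_table(result)).to_csv(path, sep="\t", index=False)
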