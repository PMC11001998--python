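"""Curation of raw Ki activity records into scaled spKi labels.

Public bioactivity exports (ChEMBL-style) mix exact measurements, censored
relations ("<", "≤", ">", "≥"), unit errors and duplicate assays.  This
module applies a fixed rule set so that every (molecule, target) pair ends
up with at most one label:

* records whose units are not a molar concentration are excluded; all
  others are converted to nanomolar;
* "=" records without a value, records with neither relation nor comment,
  and comments asserting activity without a number are excluded;
* duplicate exact measurements differing by more than one order of
  magnitude resolve to the most recent one, otherwise to the geometric
  mean;
* "<"/"≤" records (activity below a threshold) are kept as an upper bound
  only when no exact measurement exists, using the highest such threshold;
* ">"/"≥" records imply inactivity, so the pair is labeled not active
  unless an exact measurement exists.

The resolved Ki (nM) is mapped to the scaled-pKi score

    spKi = 0                    if Ki ≥ 10,000 nM or inactive
         = 1                    if Ki ≤ 1.0 nM
         = (4 − log10 Ki) / 4   otherwise

so labels live on a linear [0, 1] potency scale: 1 for sub-nanomolar
binders, 0 for physiologically inactive compounds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPKI_ACTIVE_NM = 1.0        # Ki at or below this scores 1.0
SPKI_INACTIVE_NM = 10_000.0  # Ki at or above this scores 0.0

RAW_COLUMNS = [
    "molecule_id", "target_id", "activity_type",
    "relation", "value", "units", "comment", "year",
]


class Relation(str, Enum):
    EQ = "eq"
    LT = "lt"
    LE = "le"
    GT = "gt"
    GE = "ge"
    NONE = "none"

    @classmethod
    def parse(cls, text) -> "Relation":
        if text is None or (isinstance(text, float) and math.isnan(text)):
            return cls.NONE
        mapping = {
            "=": cls.EQ, "eq": cls.EQ,
            "<": cls.LT, "lt": cls.LT,
            "<=": cls.LE, "≤": cls.LE, "le": cls.LE,
            ">": cls.GT, "gt": cls.GT,
            ">=": cls.GE, "≥": cls.GE, "ge": cls.GE,
            "": cls.NONE, "none": cls.NONE,
        }
        key = str(text).strip().lower()
        if key not in mapping:
            raise ValueError(f"unrecognized activity relation {text!r}")
        return mapping[key]


class Provenance(str, Enum):
    MEASURED = "measured"
    UPPER_BOUND = "upper_bound"
    INACTIVE_BY_RELATION = "inactive_by_relation"


@dataclass(frozen=True)
class RawActivityRecord:
    molecule_id: str
    target_id: str
    activity_type: str
    relation: Relation
    value: Optional[float]
    units: str
    comment: Optional[str] = None
    year: int = 0

    def __post_init__(self) -> None:
        if self.value is not None and self.value < 0:
            raise ValueError("activity value must be non-negative")


@dataclass(frozen=True)
class CuratedActivity:
    molecule_id: str
    target_id: str
    ki_nM: Optional[float]  # None for inactive-by-relation pairs
    spki: float
    provenance: Provenance


# Molar-concentration units accepted, with factor to nM.
_UNIT_TO_NM = {
    "m": 1e9, "mm": 1e6, "um": 1e3, "µm": 1e3, "μm": 1e3, "nm": 1.0, "pm": 1e-3,
}


def spki(ki_nM: Optional[float] = None, inactive: bool = False) -> float:
    """Scaled-pKi potency score in [0, 1] for a Ki in nM."""
    if inactive:
        return 0.0
    if ki_nM is None:
        raise ValueError("ki_nM required unless inactive")
    if ki_nM <= 0:
        raise ValueError(f"Ki must be positive, got {ki_nM}")
    if ki_nM >= SPKI_INACTIVE_NM:
        return 0.0
    if ki_nM <= SPKI_ACTIVE_NM:
        return 1.0
    return (4.0 - math.log10(ki_nM)) / 4.0


def spki_to_ki(score: float) -> float:
    """Inverse of :func:`spki` on the open interval (0, 1): Ki = 10^(4−4·spKi).

    At the clamped boundaries the inverse is not unique; 0 and 1 map to the
    representative values 10,000 nM and 1.0 nM.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError("spKi score must be in [0, 1]")
    return 10.0 ** (4.0 - 4.0 * score)


def standardize_units(
    record: RawActivityRecord,
) -> tuple[Optional[RawActivityRecord], Optional[str]]:
    """Convert a record's value to nM, or return (None, reason) if excluded.

    Recognized units are molar concentrations (M, mM, µM, nM, pM); anything
    else — percentages, mass concentrations, blanks — is excluded.
    """
    unit_key = (record.units or "").strip().lower().replace("μ", "µ")
    factor = _UNIT_TO_NM.get(unit_key)
    if factor is None:
        return None, f"unrecognized units {record.units!r}"
    if record.value is None:
        return record if factor == 1.0 else replace(record, units="nM"), None
    return replace(record, value=record.value * factor, units="nM"), None


@dataclass
class RelationOutcome:
    """Usable measurements for one (molecule, target) group."""

    measured: list[RawActivityRecord]
    upper_bound: Optional[RawActivityRecord]
    inactive: bool
    exclusions: list[tuple[RawActivityRecord, str]]


def apply_relation_rules(records: Sequence[RawActivityRecord]) -> RelationOutcome:
    """Resolve the censored-relation rules for one (molecule, target) group.

    Exact ("=") measurements always win.  Without them, "<"/"≤" bounds give
    a single upper-bound measurement at the *highest* reported threshold
    (the least informative bound), and ">"/"≥" records mark the pair as
    inactive.  All records set aside by these rules are returned with the
    reason for their exclusion.
    """
    keys = {(r.molecule_id, r.target_id) for r in records}
    if len(keys) != 1:
        raise ValueError("records must share one (molecule, target) pair")
    measured: list[RawActivityRecord] = []
    bounds: list[RawActivityRecord] = []
    inactives: list[RawActivityRecord] = []
    exclusions: list[tuple[RawActivityRecord, str]] = []
    for r in records:
        has_value = r.value is not None
        if r.relation is Relation.EQ:
            if has_value:
                measured.append(r)
            else:
                exclusions.append((r, "eq relation without a value"))
        elif r.relation in (Relation.LT, Relation.LE):
            if has_value:
                bounds.append(r)
            else:
                exclusions.append((r, "censored relation without a value"))
        elif r.relation in (Relation.GT, Relation.GE):
            inactives.append(r)
        else:  # no relation
            comment = (r.comment or "").strip()
            if not comment:
                exclusions.append((r, "no relation and no comment"))
            else:
                exclusions.append(
                    (r, "activity comment without a measured value")
                )

    if measured:
        for b in bounds:
            exclusions.append((b, "upper bound superseded by measurement"))
        for i in inactives:
            exclusions.append((i, "inactive relation superseded by measurement"))
            logger.info(
                "conflicting '>' record for %s/%s ignored in favor of measurement",
                records[0].molecule_id, records[0].target_id,
            )
        return RelationOutcome(measured, None, False, exclusions)
    if bounds:
        top = max(bounds, key=lambda r: (r.value, r.year))
        for b in bounds:
            if b is not top:
                exclusions.append((b, "lower upper-bound not selected"))
        for i in inactives:
            exclusions.append((i, "inactive relation conflicts with upper bound"))
        return RelationOutcome([], top, False, exclusions)
    if inactives:
        return RelationOutcome([], None, True, exclusions)
    return RelationOutcome([], None, False, exclusions)


def resolve_duplicates(
    values_nM: Sequence[float], years: Sequence[int]
) -> float:
    """Resolve repeated exact measurements of one pair to a single Ki (nM).

    If the spread exceeds one order of magnitude (max/min > 10), the most
    recent measurement wins (ties: geometric mean of the tied most-recent
    values); otherwise the geometric mean of all values is used.
    """
    if len(values_nM) == 0 or len(values_nM) != len(years):
        raise ValueError("need equal, non-zero numbers of values and years")
    values = np.asarray(values_nM, dtype=float)
    if np.any(values <= 0):
        raise ValueError("Ki values must be positive")
    if len(values) == 1:
        return float(values[0])
    if values.max() / values.min() > 10.0:
        years_arr = np.asarray(years)
        latest = values[years_arr == years_arr.max()]
        if len(latest) == 1:
            return float(latest[0])
        return float(10 ** np.mean(np.log10(latest)))
    return float(10 ** np.mean(np.log10(values)))


@dataclass
class CurationResult:
    """Curated labels plus a full accounting of every raw input row."""

    curated: pd.DataFrame     # molecule_id, target_id, ki_nM, spki, provenance
    exclusions: pd.DataFrame  # every excluded raw row + reason, exactly once
    n_input: int

    def conservation_holds(self) -> bool:
        """kept rows + excluded rows == input rows."""
        return len(self.exclusions) + self.n_used == self.n_input

    @property
    def n_used(self) -> int:
        return int(self.curated["n_raw_used"].sum())


def _records_from_frame(df: pd.DataFrame) -> list[tuple[int, RawActivityRecord]]:
    records = []
    for idx, row in df.iterrows():
        value = row.get("value")
        if value is not None and (isinstance(value, float) and math.isnan(value)):
            value = None
        comment = row.get("comment")
        if isinstance(comment, float) and math.isnan(comment):
            comment = None
        records.append(
            (
                idx,
                RawActivityRecord(
                    molecule_id=str(row["molecule_id"]),
                    target_id=str(row["target_id"]),
                    activity_type=str(row.get("activity_type", "Ki")),
                    relation=Relation.parse(row.get("relation")),
                    value=None if value is None else float(value),
                    units=str(row.get("units", "")),
                    comment=comment,
                    year=int(row.get("year", 0) or 0),
                ),
            )
        )
    return records


def curate_activities(
    raw: pd.DataFrame, activity_type: str = "Ki"
) -> CurationResult:
    """Run the full curation pipeline on a raw activity table.

    Expects the columns ``molecule_id, target_id, activity_type, relation,
    value, units, comment, year``.  Returns one curated row per surviving
    (molecule, target) pair and an exclusion report in which every dropped
    raw row appears exactly once with its reason.
    """
    missing = set(RAW_COLUMNS[:2]) - set(raw.columns)
    if missing:
        raise ValueError(f"raw table missing columns {sorted(missing)}")
    raw = raw.reset_index(drop=True)
    excl_rows: list[dict] = []

    def exclude(idx: int, record: RawActivityRecord, reason: str) -> None:
        excl_rows.append(
            {
                "row": idx,
                "molecule_id": record.molecule_id,
                "target_id": record.target_id,
                "reason": reason,
            }
        )

    standardized: dict[tuple[str, str], list[tuple[int, RawActivityRecord]]] = {}
    for idx, record in _records_from_frame(raw):
        if record.activity_type != activity_type:
            exclude(idx, record, f"activity type is not {activity_type}")
            continue
        converted, reason = standardize_units(record)
        if converted is None:
            exclude(idx, record, reason)
            continue
        standardized.setdefault(
            (record.molecule_id, record.target_id), []
        ).append((idx, converted))

    curated_rows: list[dict] = []
    for (mol, tgt), group in standardized.items():
        index_of = {id(rec): idx for idx, rec in group}
        outcome = apply_relation_rules([rec for _idx, rec in group])
        for rec, reason in outcome.exclusions:
            exclude(index_of[id(rec)], rec, reason)
        if outcome.measured:
            ki = resolve_duplicates(
                [r.value for r in outcome.measured],
                [r.year for r in outcome.measured],
            )
            curated_rows.append(
                dict(molecule_id=mol, target_id=tgt, ki_nM=ki,
                     spki=spki(ki), provenance=Provenance.MEASURED.value,
                     n_raw_used=len(outcome.measured))
            )
        elif outcome.upper_bound is not None:
            ki = outcome.upper_bound.value
            curated_rows.append(
                dict(molecule_id=mol, target_id=tgt, ki_nM=ki,
                     spki=spki(ki), provenance=Provenance.UPPER_BOUND.value,
                     n_raw_used=1)
            )
        elif outcome.inactive:
            n_inactive = sum(
                1 for _i, r in group
                if r.relation in (Relation.GT, Relation.GE)
            )
            curated_rows.append(
                dict(molecule_id=mol, target_id=tgt, ki_nM=np.nan,
                     spki=0.0, provenance=Provenance.INACTIVE_BY_RELATION.value,
                     n_raw_used=n_inactive)
            )

    curated = pd.DataFrame(
        curated_rows,
        columns=["molecule_id", "target_id", "ki_nM", "spki",
                 "provenance", "n_raw_used"],
    )
    exclusions = pd.DataFrame(
        excl_rows, columns=["row", "molecule_id", "target_id", "reason"]
    )
    return CurationResult(curated=curated, exclusions=exclusions,
                          n_input=len(raw))


def filter_targets(
    curated: pd.DataFrame,
    min_activities: int = 40,
    min_label_spread: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop targets with too few activities or too little label variability.

    Targets need at least ``min_activities`` curated activities and an spKi
    standard deviation of at least ``min_label_spread`` to support a
    per-target model.  Returns the filtered table and a report of dropped
    targets with reasons.
    """
    dropped = []
    keep_ids = []
    for tgt, group in curated.groupby("target_id", sort=True):
        if len(group) < min_activities:
            dropped.append(
                dict(target_id=tgt, n_activities=len(group),
                     reason="fewer than minimum activities")
            )
        elif group["spki"].std(ddof=0) < min_label_spread:
            dropped.append(
                dict(target_id=tgt, n_activities=len(group),
                     reason="insufficient label variability")
            )
        else:
            keep_ids.append(tgt)
    kept = curated[curated["target_id"].isin(keep_ids)].reset_index(drop=True)
    if kept.empty:
        raise ValueError("no targets survive filtering")
    report = pd.DataFrame(
        dropped, columns=["target_id", "n_activities", "reason"]
    )
    return kept, report
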