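"""Bioactivity curation: standardize compounds, resolve units, deduplicate.

Raw bioactivity exports (one row per measurement) are collapsed to one
record per (standardized compound, target) pair. When a pair carries
measurements of several activity types, only the highest-priority type is
kept (Ki > IC50 > EC50 > Kd); duplicate pChEMBL values within the chosen
type are averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: Activity-type priority: the leftmost present type wins.
UNIT_PRIORITY = ("Ki", "IC50", "EC50", "Kd")

_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}


@dataclass(frozen=True)
class RawActivity:
    """One raw measurement: compound, target, activity type, pChEMBL value."""

    compound_id: str
    smiles: str
    target_id: str
    activity_type: str
    value: float
    year: int | None = None

    def __post_init__(self) -> None:
        if self.activity_type not in UNIT_PRIORITY:
            raise ValueError(f"unknown activity_type {self.activity_type!r}")
        if not math.isfinite(self.value):
            raise ValueError("activity value must be finite")


@dataclass(frozen=True)
class ActivityRecord:
    """One curated (compound, target) data point with an averaged pChEMBL."""

    standardized_smiles: str
    target_id: str
    pchembl: float
    year: int | None = None
    n_merged: int = 1


@dataclass
class CurationReport:
    n_raw: int = 0
    n_curated: int = 0
    n_rejected: int = 0
    rejections: dict[str, int] = field(default_factory=dict)
    rejected_rows: list[tuple[str, str]] = field(default_factory=list)

    def reject(self, compound_id: str, reason: str) -> None:
        self.n_rejected += 1
        self.rejections[reason] = self.rejections.get(reason, 0) + 1
        self.rejected_rows.append((compound_id, reason))

    def to_dict(self) -> dict:
        return {
            "n_raw": self.n_raw,
            "n_curated": self.n_curated,
            "n_rejected": self.n_rejected,
            "rejections": dict(self.rejections),
        }


def pchembl_from_concentration(value: float, unit: str) -> float:
    """Convert a concentration to a pChEMBL value (-log10 of molar).

    >>> pchembl_from_concentration(100, "nM")
    7.0
    """
    if unit not in _UNIT_TO_MOLAR:
        raise ValueError(f"unknown unit {unit!r}; expected one of {sorted(_UNIT_TO_MOLAR)}")
    if not (value > 0):
        raise ValueError("concentration must be positive")
    return -math.log10(value * _UNIT_TO_MOLAR[unit])


def select_activity_unit(records: Sequence[RawActivity]) -> list[RawActivity]:
    """Keep only measurements of the highest-priority activity type present.

    Priority is Ki > IC50 > EC50 > Kd; lower-priority measurements for the
    same pair are discarded, not averaged in.
    """
    if not records:
        raise ValueError("no records to select from")
    for unit in UNIT_PRIORITY:
        chosen = [r for r in records if r.activity_type == unit]
        if chosen:
            return chosen
    raise AssertionError("unreachable: record with unknown unit")


def aggregate_duplicates(records: Sequence[RawActivity], standardized_smiles: str | None = None) -> ActivityRecord:
    """Average duplicate pChEMBL values into a single record.

    The merged year is the earliest year present so that temporal splits
    stay conservative (a compound known early never leaks into the future
    test set).
    """
    if not records:
        raise ValueError("no records to aggregate")
    units = {r.activity_type for r in records}
    if len(units) > 1:
        raise ValueError(f"mixed activity types {sorted(units)}; run unit selection first")
    targets = {r.target_id for r in records}
    if len(targets) > 1:
        raise ValueError("records span multiple targets")
    years = [r.year for r in records if r.year is not None]
    return ActivityRecord(
        standardized_smiles=standardized_smiles if standardized_smiles is not None else records[0].smiles,
        target_id=records[0].target_id,
        pchembl=sum(r.value for r in records) / len(records),
        year=min(years) if years else None,
        n_merged=len(records),
    )


_uncharger = rdMolStandardize.Uncharger()
_fragment_chooser = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)


def standardize_compound(smiles: str) -> str:
    """Standardize a SMILES: strip salts, neutralize charges, canonicalize.

    Keeps the largest organic fragment, neutralizes protonation-state
    charges where a neutral parent exists at pH ~7 (carboxylates, ammonium
    centers), and returns canonical SMILES. Idempotent.

    Raises ValueError for unparseable input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    mol = rdMolStandardize.Cleanup(mol)
    mol = _fragment_chooser.choose(mol)
    mol = _uncharger.uncharge(mol)
    return Chem.MolToSmiles(mol)


def curate_dataset(
    raw: pd.DataFrame | Iterable[RawActivity],
    sequences: Mapping[str, str] | None = None,
) -> tuple[list[ActivityRecord], CurationReport]:
    """Run the full curation pipeline: standardize -> unit-select -> aggregate.

    Parameters
    ----------
    raw
        Either an iterable of :class:`RawActivity` or a DataFrame with
        columns ``compound_id, smiles, target_id, activity_type, pchembl``
        (or ``value`` + ``unit`` for raw concentrations) and optional
        ``year``.
    sequences
        Target id -> amino-acid sequence. When given, records whose target
        has no sequence are dropped and counted.

    Returns
    -------
    records, report
        One :class:`ActivityRecord` per surviving (compound, target) pair,
        sorted deterministically, plus a :class:`CurationReport`.
    """
    if isinstance(raw, pd.DataFrame):
        rows = _rows_from_frame(raw)
    else:
        rows = list(raw)

    report = CurationReport(n_raw=len(rows))
    std_cache: dict[str, str | None] = {}
    groups: dict[tuple[str, str], list[RawActivity]] = {}
    for row in rows:
        if sequences is not None and row.target_id not in sequences:
            report.reject(row.compound_id, "missing_sequence")
            continue
        if row.smiles not in std_cache:
            try:
                std_cache[row.smiles] = standardize_compound(row.smiles)
            except ValueError:
                std_cache[row.smiles] = None
        std = std_cache[row.smiles]
        if std is None:
            report.reject(row.compound_id, "unparseable_smiles")
            continue
        groups.setdefault((std, row.target_id), []).append(row)

    records = []
    for (std, _target), members in groups.items():
        chosen = select_activity_unit(members)
        records.append(aggregate_duplicates(chosen, standardized_smiles=std))
    records.sort(key=lambda r: (r.target_id, r.standardized_smiles))
    report.n_curated = len(records)
    return records, report


def _rows_from_frame(frame: pd.DataFrame) -> list[RawActivity]:
    rows = []
    has_pchembl = "pchembl" in frame.columns
    for rec in frame.to_dict("records"):
        year = rec.get("year")
        if year is None or (isinstance(year, float) and math.isnan(year)):
            year = None
        else:
            year = int(year)
        if has_pchembl:
            value = float(rec["pchembl"])
        else:
            value = pchembl_from_concentration(float(rec["value"]), str(rec["unit"]))
        rows.append(
            RawActivity(
                compound_id=str(rec.get("compound_id", "")),
                smiles=str(rec["smiles"]),
                target_id=str(rec["target_id"]),
                activity_type=str(rec["activity_type"]),
                value=value,
                year=year,
            )
        )
    return rows


def records_to_frame(records: Sequence[ActivityRecord]) -> pd.DataFrame:
    """Curated records as a DataFrame (round-trips through curate_dataset)."""
    return pd.DataFrame(
        {
            "compound_id": [f"c{i}" for i in range(len(records))],
            "smiles": [r.standardized_smiles for r in records],
            "target_id": [r.target_id for r in records],
            "activity_type": ["Ki"] * len(records),
            "pchembl": [r.pchembl for r in records],
            "year": [r.year for r in records],
            "n_merged": [r.n_merged for r in records],
        }
    )
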