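"""Molecule-table and prediction I/O plus the shared domain records.

A dataset is a list of :class:`MoleculeRecord`, one per compound. Structures
are canonicalised on load, so duplicate detection and cross-set uniqueness
checks can compare SMILES strings directly. Rows whose SMILES fails to parse
are reported via logging and skipped, never silently dropped.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger

logger = logging.getLogger(__name__)

# RDKit is chatty about every sanitisation issue; surface problems through
# our own logging instead.
RDLogger.DisableLog("rdApp.*")


class ConfigurationError(ValueError):
    """Raised for malformed configuration or input schemas."""


class InputError(ValueError):
    """Raised when input data is structurally valid but unusable."""


class Call(str, enum.Enum):
    """Binary hERG activity call."""

    ACTIVE = "active"
    INACTIVE = "inactive"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Source(str, enum.Enum):
    """Provenance of a training compound: broad public or narrow private."""

    PUBLIC = "public"
    PRIVATE = "private"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ActivityKind(str, enum.Enum):
    IC50 = "IC50"
    EC50 = "EC50"
    KI = "Ki"
    PERCENT_INHIBITION = "percent_inhibition_at_10uM"
    AUTHOR_CALL = "author_call"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Kinds whose value is a potency in micromolar (lower = more potent).
POTENCY_KINDS = frozenset({ActivityKind.IC50, ActivityKind.EC50, ActivityKind.KI})


@dataclass(frozen=True)
class ActivityMeasurement:
    """One raw bioactivity observation for a compound.

    ``value`` is in micromolar for potency kinds, percent for inhibition at
    10 uM, and 0/1 for a qualitative author call.
    """

    kind: ActivityKind
    value: float

    def __post_init__(self) -> None:
        if self.kind in POTENCY_KINDS and self.value < 0:
            raise InputError(f"negative potency value {self.value} for {self.kind}")
        if self.kind is ActivityKind.PERCENT_INHIBITION and not 0 <= self.value <= 100:
            raise InputError(f"percent inhibition {self.value} outside [0, 100]")


@dataclass
class MoleculeRecord:
    """A single compound with structure, provenance and activity data."""

    id: str
    smiles: str
    source: Source | None = None
    activities: list[ActivityMeasurement] = field(default_factory=list)
    call: Call | None = None
    date: _dt.date | None = None

    def copy(self) -> "MoleculeRecord":
        return dataclasses.replace(self, activities=list(self.activities))


@dataclass
class Prediction:
    """A binary call with a confidence and its provenance.

    ``confidence`` is numeric in [0, 1] for the statistical models and
    ``None`` for the structural-alert expert, whose confidence is the
    categorical matched/no-match level recorded in ``provenance``.
    """

    id: str
    call: Call
    confidence: float | None
    model: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise InputError(f"confidence {self.confidence} outside [0, 1]")


def canonical_smiles(smiles: str) -> str | None:
    """Canonical isomeric SMILES, or ``None`` if the input does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def mol_from_record(record: MoleculeRecord) -> Chem.Mol:
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:  # canonicalised on load, so this indicates corruption
        raise InputError(f"record {record.id}: SMILES no longer parses")
    return mol


def _parse_date(raw: object) -> _dt.date | None:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    if isinstance(raw, _dt.date):
        return raw
    text = str(raw).strip()
    if not text or text.lower() == "nan":
        return None
    return _dt.date.fromisoformat(text[:10])


def _parse_call(raw: object) -> Call | None:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    text = str(raw).strip().lower()
    if not text or text == "nan":
        return None
    return Call(text)


def read_molecule_table(path: str | Path, format: str = "csv") -> list[MoleculeRecord]:
    """Read a molecule table from CSV or SDF into :class:`MoleculeRecord`s.

    The CSV schema requires ``id`` and ``smiles`` columns; optional columns
    are ``activity_kind``, ``activity_value``, ``source``, ``date`` and
    ``call``. Several rows may share an ``id``: their measurements are
    collected onto one record. Unparseable structures are logged and skipped.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if format == "csv":
        records = _read_csv(path)
    elif format == "sdf":
        records = _read_sdf(path)
    else:
        raise ConfigurationError(f"unknown molecule table format {format!r}")
    if not records:
        raise InputError(f"{path}: no parseable molecule rows")
    return records


def _read_csv(path: Path) -> list[MoleculeRecord]:
    frame = pd.read_csv(path, dtype={"id": str})
    missing = {"id", "smiles"} - set(frame.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing mandatory columns {sorted(missing)}")
    records: dict[str, MoleculeRecord] = {}
    skipped = 0
    for row in frame.itertuples(index=False):
        rid = str(row.id)
        smiles = canonical_smiles(str(row.smiles))
        if smiles is None:
            skipped += 1
            logger.warning("%s: skipping row id=%s, unparseable SMILES %r", path, rid, row.smiles)
            continue
        rec = records.get(rid)
        if rec is None:
            rec = MoleculeRecord(id=rid, smiles=smiles)
            if hasattr(row, "source") and not pd.isna(row.source):
                rec.source = Source(str(row.source).strip().lower())
            if hasattr(row, "date"):
                rec.date = _parse_date(row.date)
            if hasattr(row, "call"):
                rec.call = _parse_call(row.call)
            records[rid] = rec
        if hasattr(row, "activity_kind") and not pd.isna(row.activity_kind):
            kind = ActivityKind(str(row.activity_kind).strip())
            rec.activities.append(ActivityMeasurement(kind, float(row.activity_value)))
    if skipped:
        logger.warning("%s: skipped %d unparseable rows", path, skipped)
    return list(records.values())


def _read_sdf(path: Path) -> list[MoleculeRecord]:
    records: list[MoleculeRecord] = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("%s: skipping unparseable SDF entry %d", path, i)
            continue
        rid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf_{i}"
        rec = MoleculeRecord(id=rid, smiles=Chem.MolToSmiles(mol))
        if mol.HasProp("source"):
            rec.source = Source(mol.GetProp("source").strip().lower())
        if mol.HasProp("date"):
            rec.date = _parse_date(mol.GetProp("date"))
        records.append(rec)
    return records


def write_molecule_table(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    """Write records back to the CSV schema accepted by `read_molecule_table`."""
    rows = []
    for rec in records:
        base = {
            "id": rec.id,
            "smiles": rec.smiles,
            "source": rec.source.value if rec.source else "",
            "date": rec.date.isoformat() if rec.date else "",
            "call": rec.call.value if rec.call else "",
        }
        if rec.activities:
            for act in rec.activities:
                rows.append({**base, "activity_kind": act.kind.value, "activity_value": act.value})
        else:
            rows.append({**base, "activity_kind": "", "activity_value": ""})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_predictions(predictions: Sequence[Prediction], path: str | Path) -> None:
    """Write predictions to CSV (columns id, call, confidence, model, provenance).

    Confidences are serialised with six decimal places so round-trips through
    the file are lossless at the precision the models report.
    """
    if not predictions:
        raise InputError("no predictions to write")
    frame = pd.DataFrame(
        {
            "id": [p.id for p in predictions],
            "call": [p.call.value for p in predictions],
            "confidence": ["" if p.confidence is None else f"{p.confidence:.6f}" for p in predictions],
            "model": [p.model for p in predictions],
            "provenance": [p.provenance for p in predictions],
        }
    )
    frame.to_csv(path, index=False)


def read_predictions(path: str | Path) -> list[Prediction]:
    frame = pd.read_csv(path, dtype={"id": str}, keep_default_na=False)
    missing = {"id", "call", "confidence", "model"} - set(frame.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing prediction columns {sorted(missing)}")
    preds = []
    for row in frame.itertuples(index=False):
        conf = None if row.confidence == "" else float(row.confidence)
        preds.append(
            Prediction(
                id=str(row.id),
                call=Call(row.call),
                confidence=conf,
                model=str(row.model),
                provenance=str(getattr(row, "provenance", "")),
            )
        )
    return preds


def iter_mols(records: Iterable[MoleculeRecord]) -> Iterable[tuple[MoleculeRecord, Chem.Mol]]:
    for rec in records:
        yield rec, mol_from_record(rec)
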