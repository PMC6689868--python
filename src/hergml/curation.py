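"""Binarisation of heterogeneous bioactivities and temporal train/test splits.

Public bioactivity collections mix potencies (IC50/EC50/Ki, micromolar),
single-concentration percent-inhibition screens and qualitative author calls.
Each measurement is reduced to an active/inactive call under a
:class:`ThresholdPolicy` (10 uM potency equivalent, 50% inhibition at 10 uM
by default), and per-compound calls are merged conservatively: one active
measurement makes the compound active. Replicated screens of the same kind
are averaged *before* binarisation, which is not the same operation as
binarising each replicate and merging — see ``merge_replicates``.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .chemio import (
    POTENCY_KINDS,
    ActivityKind,
    ActivityMeasurement,
    Call,
    ConfigurationError,
    InputError,
    MoleculeRecord,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdPolicy:
    """Activity thresholds used to binarise raw measurements.

    ``potency_threshold`` (uM) applies to IC50/EC50/Ki: a compound is active
    when its potency is strictly below the threshold. ``inhibition_threshold``
    (%) applies to percent inhibition at 10 uM: active strictly above.
    Values exactly on a threshold are inactive. ``per_kind_overrides`` maps an
    :class:`ActivityKind` to a kind-specific threshold.
    """

    potency_threshold: float = 10.0
    inhibition_threshold: float = 50.0
    per_kind_overrides: dict[ActivityKind, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        thresholds = [self.potency_threshold, self.inhibition_threshold, *self.per_kind_overrides.values()]
        if any(t <= 0 for t in thresholds):
            raise ConfigurationError("all thresholds must be positive")

    def threshold_for(self, kind: ActivityKind) -> float:
        if kind in self.per_kind_overrides:
            return self.per_kind_overrides[kind]
        if kind in POTENCY_KINDS:
            return self.potency_threshold
        if kind is ActivityKind.PERCENT_INHIBITION:
            return self.inhibition_threshold
        raise ConfigurationError(f"no threshold defined for measurement kind {kind}")


def binarize_measurement(m: ActivityMeasurement, policy: ThresholdPolicy | None = None) -> Call:
    """Reduce one measurement to an active/inactive call.

    Potencies are active strictly below threshold, inhibition strictly above;
    author calls pass through (value >= 0.5 means active).
    """
    policy = policy or ThresholdPolicy()
    if m.kind is ActivityKind.AUTHOR_CALL:
        return Call.ACTIVE if m.value >= 0.5 else Call.INACTIVE
    threshold = policy.threshold_for(m.kind)
    if m.kind in POTENCY_KINDS:
        return Call.ACTIVE if m.value < threshold else Call.INACTIVE
    return Call.ACTIVE if m.value > threshold else Call.INACTIVE


def merge_calls(calls: Sequence[Call]) -> Call:
    """Conservative merge: a single active call makes the compound active."""
    if not calls:
        raise InputError("cannot merge an empty list of calls")
    return Call.ACTIVE if Call.ACTIVE in calls else Call.INACTIVE


def merge_replicates(
    values: Sequence[float], kind: ActivityKind, policy: ThresholdPolicy | None = None
) -> Call:
    """Average replicate values of one kind, then binarise the mean.

    Mean-first is the rule for replicated single-concentration screens; it
    differs from binarising each replicate and merging conservatively (e.g.
    inhibitions [20, 60] average to 40% -> inactive, while call-merging would
    report active).
    """
    if not values:
        raise InputError("cannot merge an empty list of replicate values")
    mean = sum(values) / len(values)
    return binarize_measurement(ActivityMeasurement(kind, mean), policy)


def curate_record(record: MoleculeRecord, policy: ThresholdPolicy | None = None) -> Call:
    """Assign the compound-level call from all of its measurements.

    Replicated percent-inhibition screens are averaged first; every other
    measurement is binarised individually; the per-measurement calls are then
    merged conservatively across kinds.
    """
    policy = policy or ThresholdPolicy()
    if not record.activities:
        if record.call is not None:
            return record.call
        raise InputError(f"record {record.id} has no activities and no call")
    calls: list[Call] = []
    inhibition = [a.value for a in record.activities if a.kind is ActivityKind.PERCENT_INHIBITION]
    if inhibition:
        calls.append(merge_replicates(inhibition, ActivityKind.PERCENT_INHIBITION, policy))
    for act in record.activities:
        if act.kind is ActivityKind.PERCENT_INHIBITION:
            continue
        calls.append(binarize_measurement(act, policy))
    return merge_calls(calls)


def curate_records(
    records: Iterable[MoleculeRecord], policy: ThresholdPolicy | None = None
) -> list[MoleculeRecord]:
    """Return copies of ``records`` with the ``call`` field populated."""
    curated = []
    for rec in records:
        out = rec.copy()
        out.call = curate_record(rec, policy)
        curated.append(out)
    return curated


def temporal_split(
    records: Sequence[MoleculeRecord], cutoff: _dt.date
) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Split records by date: train on/before ``cutoff``, test strictly after.

    Emulates prospective validation: the model only ever sees compounds
    registered before the compounds it is asked to predict. Undated records
    are excluded with a warning. A canonical structure appearing on both
    sides of the cutoff is removed from the test side so that no compound
    occurs in both sets.
    """
    dated = [r for r in records if r.date is not None]
    undated = len(records) - len(dated)
    if undated:
        logger.warning("temporal_split: excluding %d records without dates", undated)
    if not dated:
        raise InputError("temporal_split requires at least one dated record")
    train = [r for r in dated if r.date <= cutoff]
    test = [r for r in dated if r.date > cutoff]
    train_structures = {r.smiles for r in train}
    clashes = [r for r in test if r.smiles in train_structures]
    if clashes:
        logger.warning(
            "temporal_split: removing %d test compounds whose structure also occurs in training: %s",
            len(clashes),
            ", ".join(r.id for r in clashes[:10]),
        )
        test = [r for r in test if r.smiles not in train_structures]
    return train, test
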