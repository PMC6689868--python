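"""Confusion-matrix statistics for binary activity calls.

All eight statistics reported throughout the benchmark tables: accuracy,
balanced accuracy, sensitivity, specificity, positive/negative predictive
value, Matthews correlation coefficient and Cohen's kappa. Metrics whose
denominator is zero are reported as 0 and flagged as degenerate rather than
propagating NaN into tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chemio import Call, InputError

METRIC_COLUMNS = ("ACC", "BA", "SENS", "SPEC", "PPV", "NPV", "MCC", "KAPPA")


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    ba: float
    sens: float
    spec: float
    ppv: float
    npv: float
    mcc: float
    kappa: float
    degenerate: tuple[str, ...] = field(default=())

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_row(self) -> dict[str, float]:
        return {
            "ACC": self.acc,
            "BA": self.ba,
            "SENS": self.sens,
            "SPEC": self.spec,
            "PPV": self.ppv,
            "NPV": self.npv,
            "MCC": self.mcc,
            "KAPPA": self.kappa,
        }


def _as_bool(value, name: str) -> bool:
    if isinstance(value, Call):
        return value is Call.ACTIVE
    if isinstance(value, str):
        return Call(value.lower()) is Call.ACTIVE
    if isinstance(value, (bool, int, np.bool_, np.integer)):
        return bool(value)
    raise InputError(f"cannot interpret {name} value {value!r} as a binary call")


def confusion(calls: Sequence, truth: Sequence) -> ConfusionMetrics:
    """Compute confusion counts and the eight derived statistics.

    ``calls`` are predictions, ``truth`` the observed labels; both accept
    :class:`Call`, "active"/"inactive" strings, or booleans (True = active).
    """
    if len(calls) != len(truth):
        raise InputError(f"length mismatch: {len(calls)} calls vs {len(truth)} truths")
    if len(calls) == 0:
        raise InputError("cannot evaluate zero predictions")
    pred = [_as_bool(c, "call") for c in calls]
    obs = [_as_bool(t, "truth") for t in truth]
    tp = sum(p and o for p, o in zip(pred, obs))
    fp = sum(p and not o for p, o in zip(pred, obs))
    tn = sum(not p and not o for p, o in zip(pred, obs))
    fn = sum(not p and o for p, o in zip(pred, obs))
    return from_counts(tp, fp, tn, fn)


def from_counts(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    n = tp + fp + tn + fn
    if n == 0:
        raise InputError("empty confusion matrix")
    degenerate: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    sens = ratio(tp, tp + fn, "SENS")
    spec = ratio(tn, tn + fp, "SPEC")
    ppv = ratio(tp, tp + fp, "PPV")
    npv = ratio(tn, tn + fn, "NPV")
    acc = (tp + tn) / n
    ba = (sens + spec) / 2
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        degenerate.append("MCC")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    p_o = acc
    p_e = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / (n * n)
    if p_e == 1.0:
        degenerate.append("KAPPA")
        kappa = 0.0
    else:
        kappa = (p_o - p_e) / (1 - p_e)
    return ConfusionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        acc=acc, ba=ba, sens=sens, spec=spec, ppv=ppv, npv=npv,
        mcc=mcc, kappa=kappa, degenerate=tuple(degenerate),
    )


def metrics_table(rows: dict[str, ConfusionMetrics], decimals: int | None = 2) -> pd.DataFrame:
    """Tabulate named models' metrics in the standard column order.

    ``decimals=2`` rounds half-to-even to display precision; pass ``None``
    for full precision.
    """
    frame = pd.DataFrame({name: m.as_row() for name, m in rows.items()}).T
    frame = frame[list(METRIC_COLUMNS)]
    if decimals is not None:
        frame = frame.round(decimals)
    frame.index.name = "model"
    return frame
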