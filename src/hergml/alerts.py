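"""Structural-alert expert surrogate: SMARTS toxicophore matching.

A deliberately small, training-free stand-in for a knowledge-based expert
system: a set of curated SMARTS patterns, each describing a structural
motif associated with hERG channel blockade. A compound matching at least
one alert is called active; the matched alert names are reported as
provenance. The expert has no numeric confidence — its confidence level is
the categorical matched / no-match outcome.

The bundled default alert set is a synthetic surrogate written for this
package's benchmarks (variations on the basic-amine-plus-aromatic hERG
pharmacophore); it is not derived from any proprietary knowledge base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

from rdkit import Chem

from .chemio import Call, InputError, MoleculeRecord, Prediction, mol_from_record

logger = logging.getLogger(__name__)

DEFAULT_ALERTS_RESOURCE = "herg_alerts.tsv"


@dataclass(frozen=True)
class StructuralAlert:
    name: str
    smarts: str
    rationale: str = ""

    @property
    def pattern(self) -> Chem.Mol:
        pat = Chem.MolFromSmarts(self.smarts)
        if pat is None:  # validated at load; only reachable via direct construction
            raise InputError(f"alert {self.name}: SMARTS does not compile: {self.smarts}")
        return pat


def _parse_alert_lines(lines: Sequence[str], origin: str) -> list[StructuralAlert]:
    alerts: list[StructuralAlert] = []
    seen: set[str] = set()
    first_content = True
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if first_content:
            first_content = False
            if [p.strip().lower() for p in parts[:2]] == ["name", "smarts"]:
                continue
        if len(parts) < 2:
            raise InputError(f"{origin}:{lineno}: expected name<TAB>smarts[<TAB>rationale]")
        name, smarts = parts[0].strip(), parts[1].strip()
        rationale = parts[2].strip() if len(parts) > 2 else ""
        if Chem.MolFromSmarts(smarts) is None:
            raise InputError(f"{origin}:{lineno}: malformed SMARTS for alert {name!r}: {smarts}")
        if name in seen:
            raise InputError(f"{origin}:{lineno}: duplicate alert name {name!r}")
        seen.add(name)
        alerts.append(StructuralAlert(name, smarts, rationale))
    if not alerts:
        raise InputError(f"{origin}: no valid alerts found")
    return alerts


def load_alerts(path: str | Path) -> list[StructuralAlert]:
    """Load a TSV alert file (columns: name, SMARTS, rationale)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such alert file: {path}")
    return _parse_alert_lines(path.read_text().splitlines(), str(path))


def default_alerts() -> list[StructuralAlert]:
    """The bundled synthetic surrogate alert set (five hERG-flavoured patterns)."""
    text = resources.files("hergml").joinpath("data", DEFAULT_ALERTS_RESOURCE).read_text()
    return _parse_alert_lines(text.splitlines(), DEFAULT_ALERTS_RESOURCE)


def matched_alerts(alerts: Sequence[StructuralAlert], mol: Chem.Mol) -> list[str]:
    return [a.name for a in alerts if mol.HasSubstructMatch(a.pattern)]


def expert_predict(alerts: Sequence[StructuralAlert], query: MoleculeRecord) -> Prediction:
    """Call a compound active iff at least one alert matches as a substructure.

    The returned prediction carries no numeric confidence; provenance is
    ``matched:<names>`` or ``no_match``.
    """
    if not alerts:
        raise InputError("empty alert set")
    mol = mol_from_record(query)
    hits = matched_alerts(alerts, mol)
    if hits:
        return Prediction(query.id, Call.ACTIVE, None, "expert", provenance="matched:" + ",".join(hits))
    return Prediction(query.id, Call.INACTIVE, None, "expert", provenance="no_match")


def expert_predict_all(
    alerts: Sequence[StructuralAlert], records: Sequence[MoleculeRecord]
) -> list[Prediction]:
    return [expert_predict(alerts, r) for r in records]
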