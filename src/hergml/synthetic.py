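"""Synthetic two-source hERG-like benchmark data with planted toxicophores.

Molecules are assembled by splicing decoration fragments onto a curated
scaffold library, so that planted motifs occur at controllable topological
distances and every structure is chemically valid. Two data sources emulate
the public/private asymmetry of real hERG collections:

* the *public* source samples the full scaffold library (mostly outside the
  private space) and carries high label noise, emulating a broad,
  heterogeneous literature compilation;
* the *private* source is confined to a narrow core-scaffold subset with
  low label noise, emulating a single-protocol corporate screen.

Activity is driven by a shared mechanism: each molecule's true label is
Bernoulli with logit = base + sum of the effects of the planted motifs it
contains. Observed labels flip with a per-source noise rate. The private
data is split temporally, and the late-period test set is composed with a
configurable negative bias (default 75% inactive), emulating prospective
validation on compounds designed to avoid known liabilities. The default
second motif is common in public data and in the late test period but rare
in the private training window — the "unexpected actives" a private-only
model cannot know about.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from . import features as _feat
from .chemio import (
    ActivityKind,
    ActivityMeasurement,
    Call,
    ConfigurationError,
    MoleculeRecord,
    Source,
)
from .features import AtomPairFeature

# Private ("core") chemical space: the first CORE_SCAFFOLDS entries.
SCAFFOLDS: tuple[str, ...] = (
    "c1ccccc1",
    "c1ccncc1",
    "c1ccc2ccccc2c1",
    "c1ccc2c(c1)cccn2",
    "C1CCCCC1",
    "c1ccc(-c2ccccc2)cc1",
    "c1ccoc1",
    "c1ccsc1",
    # peripheral space (public only, mostly)
    "c1cncnc1",
    "c1cnccn1",
    "c1ccnnc1",
    "c1c[nH]cn1",
    "c1cc[nH]n1",
    "c1ocnc1",
    "c1scnc1",
    "c1cc[nH]c1",
    "c1ccc2c(c1)cc[nH]2",
    "c1ccc2c(c1)cco2",
    "c1ccc2c(c1)ccs2",
    "C1CCCC1",
    "C1CCCCCC1",
    "C1CCOC1",
    "C1CCOCC1",
    "C1CCNCC1",
    "C1CCNC1",
    "C1COCCN1",
    "C1CC2CCC1C2",
    "CC1CCCCC1",
    "O=C1CCCCC1",
    "c1ccc(COc2ccccc2)cc1",
)
CORE_SCAFFOLDS = 8

#: Decoration fragments: (SMILES, attachment atom index).
DECORATIONS: tuple[tuple[str, int], ...] = (
    ("C", 0), ("CC", 0), ("CCC", 0), ("C(C)C", 0), ("C(C)(C)C", 0),
    ("C=C", 0), ("CC=C", 0), ("C#N", 0), ("C(F)(F)F", 0),
    ("F", 0), ("Cl", 0), ("Br", 0),
    ("O", 0), ("OC", 0), ("OCC", 0), ("OC(C)C", 0), ("CO", 0), ("CCO", 0),
    ("N", 0), ("CN", 0), ("CCN", 0), ("NC(C)=O", 0), ("C(N)=O", 0),
    ("C(=O)O", 0), ("C(=O)OC", 0), ("C(C)=O", 0), ("C=O", 0),
    ("S", 0), ("SC", 0), ("S(C)(=O)=O", 0), ("S(N)(=O)=O", 0),
    ("c1ccccc1", 0), ("Cc1ccccc1", 0), ("OCc1ccccc1", 0),
    ("C1CC1", 0), ("CC1CC1", 0), ("CN1CCOCC1", 0), ("N1CCOCC1", 0),
    ("OCCO", 0), ("CC(C)O", 0),
)


@dataclass(frozen=True)
class PlantedMotif:
    """A toxicophoric fragment spliced into a molecule with some prevalence.

    ``effect`` is the additive contribution to the activity logit when the
    motif is present; prevalences may differ per source, which is how the
    benchmark plants "unexpected actives" that only public data covers.
    """

    name: str
    smiles: str
    attach_idx: int = 0
    effect: float = 2.5
    p_public: float = 0.3
    p_private_train: float = 0.3
    p_private_test: float = 0.3


DEFAULT_MOTIFS: tuple[PlantedMotif, ...] = (
    # the "known" pharmacophore: a basic amine, well covered by both sources
    # and by the alert surrogate
    PlantedMotif("dimethylaminoethyl", "CCN(C)C", 0, 2.5, 0.35, 0.35, 0.35),
    # the "unexpected" trigger: structurally unrelated to the amine
    # pharmacophore, common in public data and in the late test period but
    # essentially absent from the private training window
    PlantedMotif("phenylthioethyl", "CCSc1ccccc1", 0, 2.5, 0.30, 0.01, 0.30),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic benchmark (desk-scale defaults)."""

    n_public: int = 900
    n_private_train: int = 400
    n_private_test: int = 316
    motifs: tuple[PlantedMotif, ...] = DEFAULT_MOTIFS
    base_logit: float = -1.5
    scaffold_effect_sd: float = 1.5
    label_flip_public: float = 0.15
    label_flip_private: float = 0.05
    scaffold_overlap: float = 0.10
    test_negative_bias: float = 0.75
    date_start: _dt.date = _dt.date(2010, 3, 25)
    date_end: _dt.date = _dt.date(2017, 6, 23)
    split_date: _dt.date = _dt.date(2017, 4, 13)
    max_decorations: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [self.label_flip_public, self.label_flip_private, self.scaffold_overlap,
                 self.test_negative_bias]
        probs += [p for m in self.motifs for p in (m.p_public, m.p_private_train, m.p_private_test)]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("all probabilities must lie in [0, 1]")
        if min(self.n_public, self.n_private_train, self.n_private_test) < 1:
            raise ConfigurationError("sample sizes must be >= 1")
        if not self.date_start <= self.split_date <= self.date_end:
            raise ConfigurationError("split date must lie inside the date range")


@dataclass
class SyntheticDataset:
    public: list[MoleculeRecord]
    private_train: list[MoleculeRecord]
    private_test: list[MoleculeRecord]
    ground_truth: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def all_records(self) -> list[MoleculeRecord]:
        return [*self.public, *self.private_train, *self.private_test]


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _assemble(
    rng: np.random.Generator,
    scaffold: str,
    fragments: Sequence[tuple[str, int]],
) -> str | None:
    """Splice fragments onto random decorable carbons; canonical SMILES or None."""
    mol = Chem.MolFromSmiles(scaffold)
    for frag_smiles, attach_idx in fragments:
        frag = Chem.MolFromSmiles(frag_smiles)
        if frag is None:
            raise ConfigurationError(f"fragment {frag_smiles!r} does not parse")
        sites = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetSymbol() == "C" and a.GetTotalNumHs() > 0
        ]
        if not sites:
            return None
        pos = int(rng.choice(sites))
        offset = mol.GetNumAtoms()
        combined = Chem.RWMol(Chem.CombineMols(mol, frag))
        combined.AddBond(pos, offset + attach_idx, Chem.BondType.SINGLE)
        try:
            mol = combined.GetMol()
            Chem.SanitizeMol(mol)
        except Exception:
            return None
    return Chem.MolToSmiles(mol)


def _draw_molecule(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    motif_probs: Sequence[float],
    core_only: bool,
) -> tuple[str, list[bool], int]:
    """One valid, assembled molecule plus its motif flags and scaffold index."""
    for _ in range(50):
        if core_only or rng.random() < cfg.scaffold_overlap:
            scaffold_idx = int(rng.integers(CORE_SCAFFOLDS))
        else:
            scaffold_idx = CORE_SCAFFOLDS + int(rng.integers(len(SCAFFOLDS) - CORE_SCAFFOLDS))
        scaffold = SCAFFOLDS[scaffold_idx]
        flags = [bool(rng.random() < p) for p in motif_probs]
        # decorations first, motifs last: nothing may later decorate a motif
        # atom and change its typed environment
        n_dec = int(rng.integers(1, cfg.max_decorations + 1))
        frags: list[tuple[str, int]] = [
            DECORATIONS[int(j)] for j in rng.integers(0, len(DECORATIONS), size=n_dec)
        ]
        frags.extend((m.smiles, m.attach_idx) for m, f in zip(cfg.motifs, flags) if f)
        smiles = _assemble(rng, scaffold, frags)
        if smiles is not None:
            return smiles, flags, scaffold_idx
    raise ConfigurationError("could not assemble a valid molecule in 50 attempts")


def _true_label(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    flags: Sequence[bool],
    scaffold_effect: float,
) -> bool:
    logit = cfg.base_logit + scaffold_effect
    logit += sum(m.effect for m, f in zip(cfg.motifs, flags) if f)
    return bool(rng.random() < _sigmoid(logit))


def _observe(rng: np.random.Generator, true_label: bool, flip_rate: float) -> tuple[bool, bool]:
    flipped = bool(rng.random() < flip_rate)
    return (not true_label if flipped else true_label), flipped


def _random_date(rng: np.random.Generator, start: _dt.date, end: _dt.date) -> _dt.date:
    span = (end - start).days
    return start + _dt.timedelta(days=int(rng.integers(span + 1)))


def _activity(rng: np.random.Generator, observed_active: bool) -> ActivityMeasurement:
    value = rng.uniform(55.0, 95.0) if observed_active else rng.uniform(5.0, 45.0)
    return ActivityMeasurement(ActivityKind.PERCENT_INHIBITION, float(value))


def generate_dataset(cfg: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate the public / private-train / private-test benchmark datasets.

    Fully reproducible from ``cfg.seed``; the three datasets use independent
    derived random streams. Canonical structures are unique within each
    dataset and across the private train/test pair.
    """
    cfg = cfg or SimulationConfig()
    streams = np.random.SeedSequence(cfg.seed).spawn(4)
    rng_mech, rng_pub, rng_train, rng_test = (np.random.default_rng(s) for s in streams)
    # series-dependent activity baselines, shared by all three datasets
    scaffold_effects = rng_mech.normal(0.0, cfg.scaffold_effect_sd, len(SCAFFOLDS))
    rows: list[dict] = []

    def make_records(
        rng: np.random.Generator,
        n: int,
        dataset: str,
        source: Source,
        motif_probs: list[float],
        core_only: bool,
        flip_rate: float,
        date_lo: _dt.date,
        date_hi: _dt.date,
        taken: set[str],
        quota: tuple[int, int] | None = None,
    ) -> list[MoleculeRecord]:
        records: list[MoleculeRecord] = []
        need_neg, need_pos = quota if quota else (None, None)
        attempts = 0
        limit = 80 * n
        while len(records) < n:
            attempts += 1
            if attempts > limit:
                raise ConfigurationError(
                    f"{dataset}: could not reach {n} unique compounds"
                    + (" under the configured negative bias" if quota else "")
                )
            smiles, flags, scaffold_idx = _draw_molecule(rng, cfg, motif_probs, core_only)
            if smiles in taken:
                continue
            y_true = _true_label(rng, cfg, flags, scaffold_effects[scaffold_idx])
            observed, flipped = _observe(rng, y_true, flip_rate)
            if quota:
                if observed and need_pos <= 0:
                    continue
                if not observed and need_neg <= 0:
                    continue
                if observed:
                    need_pos -= 1
                else:
                    need_neg -= 1
            taken.add(smiles)
            rid = f"{dataset}_{len(records) + 1:05d}"
            rec = MoleculeRecord(
                id=rid,
                smiles=smiles,
                source=source,
                activities=[_activity(rng, observed)],
                call=Call.ACTIVE if observed else Call.INACTIVE,
                date=_random_date(rng, date_lo, date_hi),
            )
            records.append(rec)
            rows.append(
                {
                    "id": rid,
                    "dataset": dataset,
                    "smiles": smiles,
                    "scaffold": SCAFFOLDS[scaffold_idx],
                    "scaffold_effect": scaffold_effects[scaffold_idx],
                    **{f"motif_{m.name}": f for m, f in zip(cfg.motifs, flags)},
                    "true_label": y_true,
                    "observed_label": observed,
                    "flipped": flipped,
                }
            )
        return records

    public = make_records(
        rng_pub, cfg.n_public, "public", Source.PUBLIC,
        [m.p_public for m in cfg.motifs], core_only=False,
        flip_rate=cfg.label_flip_public,
        date_lo=cfg.date_start, date_hi=cfg.date_end, taken=set(),
    )
    private_taken: set[str] = set()
    private_train = make_records(
        rng_train, cfg.n_private_train, "private_train", Source.PRIVATE,
        [m.p_private_train for m in cfg.motifs], core_only=True,
        flip_rate=cfg.label_flip_private,
        date_lo=cfg.date_start, date_hi=cfg.split_date, taken=private_taken,
    )
    n_neg = int(round(cfg.test_negative_bias * cfg.n_private_test))
    private_test = make_records(
        rng_test, cfg.n_private_test, "private_test", Source.PRIVATE,
        [m.p_private_test for m in cfg.motifs], core_only=True,
        flip_rate=cfg.label_flip_private,
        date_lo=cfg.split_date + _dt.timedelta(days=1), date_hi=cfg.date_end,
        taken=private_taken,
        quota=(n_neg, cfg.n_private_test - n_neg),
    )
    return SyntheticDataset(
        public=public,
        private_train=private_train,
        private_test=private_test,
        ground_truth=pd.DataFrame(rows),
        config=cfg,
    )


def ground_truth_report(dataset: SyntheticDataset) -> pd.DataFrame:
    """Per-molecule motif flags and pre-noise labels, for recovery tests."""
    return dataset.ground_truth.copy()


def motif_signature_features(
    motif: PlantedMotif,
    d_min: int = _feat.PAIR_MIN_DISTANCE,
    d_max: int = _feat.PAIR_MAX_DISTANCE,
) -> set[AtomPairFeature]:
    """Atom-pair features intrinsic to a motif, independent of the scaffold.

    The fragment is capped at its attachment point with a single sp3 carbon
    (the same element environment any scaffold attachment provides), and
    only pairs internal to the fragment are kept. Any of these features
    identifies the planted toxicophore.
    """
    frag = Chem.MolFromSmiles(motif.smiles)
    capped = Chem.RWMol(frag)
    cap = capped.AddAtom(Chem.Atom(6))
    capped.AddBond(motif.attach_idx, cap, Chem.BondType.SINGLE)
    mol = capped.GetMol()
    Chem.SanitizeMol(mol)
    types = _feat.type_atoms(mol)
    dmat = Chem.GetDistanceMatrix(mol)
    n_frag = frag.GetNumAtoms()
    out: set[AtomPairFeature] = set()
    for i in range(n_frag):
        for j in range(i + 1, n_frag):
            d = int(round(dmat[i, j]))
            if d_min <= d <= d_max:
                out.add(AtomPairFeature.make(types[i], types[j], d))
    return out


def with_seed(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(cfg, seed=seed)
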