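"""Molecular features: typed atom pairs, Morgan fingerprints, descriptors.

The atom-pair representation describes a molecule as the set of unordered
pairs of *typed* heavy atoms together with their shortest topological
(bond-count) distance, for distances between 2 and 20 bonds. The atom type
refines the element with aromaticity, hybridisation and the multiset of
directly bonded heavy-atom elements, in the spirit of environment-refined
Ghose–Crippen typing; formal charge is deliberately ignored. Two atoms in
identical local environments always receive the same code, and typing is
invariant to atom ordering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from rdkit.DataStructs.cDataStructs import ExplicitBitVect

from .chemio import InputError

logger = logging.getLogger(__name__)

PAIR_MIN_DISTANCE = 2
PAIR_MAX_DISTANCE = 20
FP_RADIUS = 4
FP_WIDTH = 4096


@dataclass(frozen=True, order=True)
class AtomPairFeature:
    """An unordered typed atom pair at a shortest-path bond distance.

    ``type_a <= type_b`` lexicographically so that the pair is canonical.
    """

    type_a: str
    type_b: str
    distance: int

    def __post_init__(self) -> None:
        if self.type_a > self.type_b:
            raise InputError("AtomPairFeature types must be in canonical (sorted) order")

    @classmethod
    def make(cls, type_a: str, type_b: str, distance: int) -> "AtomPairFeature":
        a, b = sorted((type_a, type_b))
        return cls(a, b, int(distance))

    @property
    def code(self) -> str:
        return f"{self.type_a}~{self.type_b}@{self.distance}"

    @classmethod
    def from_code(cls, code: str) -> "AtomPairFeature":
        pair, _, dist = code.rpartition("@")
        a, _, b = pair.partition("~")
        return cls(a, b, int(dist))


def type_atoms(mol: Chem.Mol) -> list[str]:
    """One environment-refined type code per heavy atom.

    The code is ``element.aromaticity-or-hybridisation[sorted neighbour
    elements]``, e.g. the ethanol carbinol carbon is ``C.sp3[CO]`` while its
    methyl carbon is ``C.sp3[C]``.
    """
    codes = []
    for atom in mol.GetAtoms():
        env = "ar" if atom.GetIsAromatic() else str(atom.GetHybridization()).lower()
        neighbours = "".join(sorted(n.GetSymbol() for n in atom.GetNeighbors()))
        codes.append(f"{atom.GetSymbol()}.{env}[{neighbours}]")
    return codes


def enumerate_atom_pairs(
    mol: Chem.Mol, d_min: int = PAIR_MIN_DISTANCE, d_max: int = PAIR_MAX_DISTANCE
) -> set[AtomPairFeature]:
    """All typed atom-pair features at shortest-path distance in [d_min, d_max].

    Distances are topological bond counts over heavy atoms; disconnected
    atom pairs are not features.
    """
    if not 1 <= d_min <= d_max:
        raise InputError(f"invalid distance range [{d_min}, {d_max}]")
    types = type_atoms(mol)
    dmat = Chem.GetDistanceMatrix(mol)
    features: set[AtomPairFeature] = set()
    n = mol.GetNumAtoms()
    for i in range(n):
        for j in range(i + 1, n):
            d = dmat[i, j]
            if not math.isfinite(d):
                continue
            d = int(round(d))
            if d_min <= d <= d_max:
                features.add(AtomPairFeature.make(types[i], types[j], d))
    return features


_FP_GENERATORS: dict[tuple[int, int, bool], object] = {}


def _generator(radius: int, width: int, feature_variant: bool):
    key = (radius, width, feature_variant)
    if key not in _FP_GENERATORS:
        invariants = rdFingerprintGenerator.GetMorganFeatureAtomInvGen() if feature_variant else None
        _FP_GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=width, atomInvariantsGenerator=invariants
        )
    return _FP_GENERATORS[key]


def morgan_fingerprint(
    mol: Chem.Mol,
    radius: int = FP_RADIUS,
    width: int = FP_WIDTH,
    feature_variant: bool = False,
) -> ExplicitBitVect:
    """Circular (Morgan) fingerprint as a fixed-width bit vector.

    ``feature_variant`` switches to pharmacophoric feature invariants
    (the "feature Morgan" variant).
    """
    return _generator(radius, width, feature_variant).GetFingerprint(mol)


def fingerprint_from_bits(bits: Sequence[int], width: int = FP_WIDTH) -> ExplicitBitVect:
    """Construct a fingerprint with the given on-bits (mainly for tests)."""
    fp = ExplicitBitVect(width)
    for b in bits:
        fp.SetBit(int(b))
    return fp


def tanimoto(a: ExplicitBitVect, b: ExplicitBitVect) -> float:
    """Tanimoto similarity |a&b| / |a|b| between equal-width fingerprints.

    Two all-zero fingerprints have no shared evidence; their similarity is
    defined as 0 with a warning rather than the indeterminate 0/0.
    """
    if a.GetNumBits() != b.GetNumBits():
        raise InputError(f"fingerprint width mismatch: {a.GetNumBits()} vs {b.GetNumBits()}")
    if a.GetNumOnBits() == 0 and b.GetNumOnBits() == 0:
        logger.warning("tanimoto of two empty fingerprints; defining as 0")
        return 0.0
    return DataStructs.TanimotoSimilarity(a, b)


def bulk_tanimoto(query: ExplicitBitVect, pool: Sequence[ExplicitBitVect]) -> np.ndarray:
    if not pool:
        return np.zeros(0)
    return np.asarray(DataStructs.BulkTanimotoSimilarity(query, list(pool)))


#: Default physicochemical descriptor panel (~40 standard 2D properties).
PHYSCHEM_DESCRIPTOR_NAMES: tuple[str, ...] = (
    "MolWt",
    "HeavyAtomMolWt",
    "ExactMolWt",
    "MolLogP",
    "MolMR",
    "TPSA",
    "LabuteASA",
    "HeavyAtomCount",
    "NumHAcceptors",
    "NumHDonors",
    "NumHeteroatoms",
    "NumRotatableBonds",
    "NumValenceElectrons",
    "NumAromaticRings",
    "NumSaturatedRings",
    "NumAliphaticRings",
    "NumAromaticCarbocycles",
    "NumAromaticHeterocycles",
    "NumSaturatedCarbocycles",
    "NumSaturatedHeterocycles",
    "NumAliphaticCarbocycles",
    "NumAliphaticHeterocycles",
    "RingCount",
    "FractionCSP3",
    "NHOHCount",
    "NOCount",
    "BalabanJ",
    "BertzCT",
    "Chi0",
    "Chi1",
    "Chi0n",
    "Chi1n",
    "Chi2n",
    "HallKierAlpha",
    "Kappa1",
    "Kappa2",
    "Kappa3",
    "MaxPartialCharge",
    "MinPartialCharge",
    "qed",
)

_DESCRIPTOR_FNS = {name: fn for name, fn in Descriptors.descList}


def physchem_descriptors(
    mol: Chem.Mol, names: Sequence[str] = PHYSCHEM_DESCRIPTOR_NAMES
) -> np.ndarray:
    """Fixed-length vector of 2D physicochemical descriptors.

    Descriptors that fail or return non-finite values (e.g. partial charges
    on exotic atoms) are imputed to 0 with a warning so downstream models
    always see finite input.
    """
    values = np.zeros(len(names))
    for i, name in enumerate(names):
        try:
            v = float(_DESCRIPTOR_FNS[name](mol))
        except Exception:
            v = float("nan")
        if not math.isfinite(v):
            logger.warning("descriptor %s non-finite for %s; imputing 0", name, Chem.MolToSmiles(mol))
            v = 0.0
        values[i] = v
    return values


def fingerprint_to_array(fp: ExplicitBitVect) -> np.ndarray:
    arr = np.zeros(fp.GetNumBits(), dtype=np.float32)
    DataStructs.ConvertToNumpyArray(fp, arr)
    return arr
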