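"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: shortest paths come
from a hand-rolled BFS rather than the toolkit distance matrix, and the
information-gain scan is a plain-Python exhaustive loop rather than the
vectorised recursive partitioner.
"""

from __future__ import annotations

import collections
import math

import numpy as np

from hergml.chemio import Call, MoleculeRecord, mol_from_record
from hergml.features import AtomPairFeature, enumerate_atom_pairs, type_atoms
from hergml.synthetic import DECORATIONS, SCAFFOLDS, _assemble


def oracle_atom_pairs(mol, d_min: int = 2, d_max: int = 20) -> set[AtomPairFeature]:
    """All-pairs shortest-path atom-pair features via breadth-first search."""
    types = type_atoms(mol)
    adj = collections.defaultdict(list)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[i].append(j)
        adj[j].append(i)
    out: set[AtomPairFeature] = set()
    for start in range(mol.GetNumAtoms()):
        dist = {start: 0}
        queue = collections.deque([start])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        for other, d in dist.items():
            if other > start and d_min <= d <= d_max:
                out.add(AtomPairFeature.make(types[start], types[other], d))
    return out


def random_small_molecules(seed: int, n: int, max_heavy: int = 12) -> list:
    """Randomly assembled valid molecules with at most ``max_heavy`` atoms."""
    from rdkit import Chem

    rng = np.random.default_rng(seed)
    mols = []
    while len(mols) < n:
        scaffold = SCAFFOLDS[int(rng.integers(len(SCAFFOLDS)))]
        frags = [DECORATIONS[int(rng.integers(len(DECORATIONS)))]]
        smiles = _assemble(rng, scaffold, frags)
        if smiles is None:
            continue
        mol = Chem.MolFromSmiles(smiles)
        if mol.GetNumAtoms() <= max_heavy:
            mols.append(mol)
    return mols


def _entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))


def oracle_root_split(
    records: list[MoleculeRecord], min_support: int
) -> tuple[float | None, set[str]]:
    """Exhaustive information-gain scan over every atom-pair feature.

    Returns the maximal gain and the set of argmax feature codes (within
    1e-9), or (None, empty) when no eligible feature has positive gain.
    """
    featsets = [{f.code for f in enumerate_atom_pairs(mol_from_record(r))} for r in records]
    labels = [r.call is Call.ACTIVE for r in records]
    n, n_act = len(records), sum(labels)
    h_root = _entropy(n_act / n)
    scored: list[tuple[float, str]] = []
    for code in sorted(set().union(*featsets)):
        present = [code in fs for fs in featsets]
        n_pres = sum(present)
        if n_pres < min_support or n_pres == n:
            continue
        act_pres = sum(p and l for p, l in zip(present, labels))
        gain = h_root - (
            n_pres * _entropy(act_pres / n_pres)
            + (n - n_pres) * _entropy((n_act - act_pres) / (n - n_pres))
        ) / n
        scored.append((gain, code))
    if not scored:
        return None, set()
    gmax = max(g for g, _ in scored)
    if gmax <= 1e-9:
        return None, set()
    return gmax, {c for g, c in scored if g >= gmax - 1e-9}
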