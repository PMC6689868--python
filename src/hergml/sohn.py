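"""Self-organising hypothesis network (SOHN) classifier.

The presence of a typed atom pair in a molecule is a candidate toxicophoric
hypothesis. Training selects the most informative hypotheses by recursive
partitioning: at each node the atom-pair feature with the highest Shannon
information gain splits the node's compounds into present/absent subsets
until purity, a minimum-support floor, or a maximum depth is reached. The
selected hypotheses, each carrying the set of training compounds that
contain its feature, are organised into a Hasse diagram under strict
support-set inclusion: a child hypothesis is a specialisation whose
supporting compounds form a strict subset of its parent's.

To predict a query compound, the most specific applicable hypotheses (those
whose feature the query contains and which have no applicable descendant)
are each evaluated as a local k-nearest-neighbour model over their
supporting compounds; the final call is that of the most confident local
model. A query matching no hypothesis is out of domain and falls back to a
global kNN over the whole training set, flagged as such.

The local confidence is the product of the mean neighbour similarity and
the fraction of neighbours agreeing with the call, anchored at exactly 1
for an exact training-set match or a unanimous neighbourhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from rdkit import Chem

from . import features as _feat
from .chemio import Call, InputError, MoleculeRecord, Prediction, mol_from_record
from .features import AtomPairFeature

logger = logging.getLogger(__name__)

_TOL = 1e-12


@dataclass(frozen=True)
class Hypothesis:
    """A selected atom-pair hypothesis with its supporting compounds.

    ``feature_codes`` normally holds a single atom-pair code; features that
    are indistinguishable on the training set (identical support and gain,
    e.g. atom pairs internal to one rigid motif) are merged into one
    hypothesis carrying all of their codes.
    """

    feature_codes: tuple[str, ...]
    support: frozenset[int]
    gain: float
    depth: int = 0

    @property
    def features(self) -> tuple[AtomPairFeature, ...]:
        return tuple(AtomPairFeature.from_code(c) for c in self.feature_codes)

    @property
    def key(self) -> str:
        return self.feature_codes[0]


@dataclass
class HypothesisNetwork:
    """Hasse diagram of hypotheses under strict support-set inclusion."""

    nodes: list[Hypothesis]
    children: dict[int, tuple[int, ...]]

    def validate(self) -> None:
        for parent, kids in self.children.items():
            for child in kids:
                if not self.nodes[child].support < self.nodes[parent].support:
                    raise InputError("network edge violates strict support inclusion")

    def descendants(self, idx: int) -> set[int]:
        out: set[int] = set()
        stack = list(self.children.get(idx, ()))
        while stack:
            j = stack.pop()
            if j not in out:
                out.add(j)
                stack.extend(self.children.get(j, ()))
        return out


@dataclass
class SohnConfig:
    min_support: int = 10
    max_depth: int = 8
    k: int = 9
    d_min: int = _feat.PAIR_MIN_DISTANCE
    d_max: int = _feat.PAIR_MAX_DISTANCE
    combine: str = "max_confidence"  # or "weighted_vote"
    seed: int = 0


def _entropy(p: np.ndarray | float) -> np.ndarray | float:
    p = np.clip(p, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(np.where(p > 0, p * np.log2(p), 0.0) + np.where(p < 1, (1 - p) * np.log2(1 - p), 0.0))
    return h


def sohn_confidence(
    similarities: Sequence[float],
    labels: Sequence[Call],
    call: Call,
    weights: Sequence[float] | None = None,
) -> float:
    """Confidence of a local kNN call in [0, 1].

    mean(similarity) * fraction-agreeing, overridden to exactly 1 when the
    query matches a training compound exactly (max similarity 1) or the
    neighbourhood is unanimous.
    """
    sims = np.asarray(similarities, dtype=float)
    if sims.size == 0 or len(labels) != sims.size:
        raise InputError("similarities and labels must be parallel and non-empty")
    w = np.ones(sims.size) if weights is None else np.asarray(weights, dtype=float)
    agree = float(w[[lab == call for lab in labels]].sum() / w.sum())
    if sims.max() >= 1.0 - 1e-9 or agree >= 1.0 - 1e-12:
        return 1.0
    return float(np.clip(sims.mean() * agree, 0.0, 1.0))


class SohnModel:
    """Trainable SOHN classifier over typed atom-pair hypotheses."""

    def __init__(self, config: SohnConfig | None = None):
        self.config = config or SohnConfig()
        self._fitted = False

    # ------------------------------------------------------------ training

    def fit(
        self,
        records: Sequence[MoleculeRecord],
        sample_weight: Sequence[float] | None = None,
    ) -> "SohnModel":
        if not records:
            raise InputError("cannot train on an empty dataset")
        if any(r.call is None for r in records):
            raise InputError("all training records need a binary call (curate first)")
        # Sort-stabilise so training is invariant to input row order.
        order = sorted(range(len(records)), key=lambda i: (records[i].smiles, records[i].id))
        self.records = [records[i] for i in order]
        if sample_weight is None:
            self.weights = np.ones(len(records))
        else:
            w = np.asarray(sample_weight, dtype=float)
            if w.shape != (len(records),) or (w < 0).any() or w.sum() <= 0:
                raise InputError("sample_weight must be non-negative with positive total")
            self.weights = w[order]
        mols = [mol_from_record(r) for r in self.records]
        self.labels = np.array([r.call == Call.ACTIVE for r in self.records], dtype=bool)
        self.fps = [_feat.morgan_fingerprint(m) for m in mols]
        cfg = self.config
        featsets = [
            {f.code for f in _feat.enumerate_atom_pairs(m, cfg.d_min, cfg.d_max)} for m in mols
        ]
        self.vocab = sorted(set().union(*featsets)) if featsets else []
        col = {c: j for j, c in enumerate(self.vocab)}
        X = np.zeros((len(records), len(self.vocab)), dtype=bool)
        for i, fs in enumerate(featsets):
            for c in fs:
                X[i, col[c]] = True
        self._matrix = X
        self.hypotheses = self._select_hypotheses(X)
        self.network = build_network(self.hypotheses)
        self.network.validate()
        self._fitted = True
        return self

    def _gain_vector(self, X: np.ndarray, idx: np.ndarray) -> np.ndarray:
        """Weighted Shannon information gain of every feature over records idx."""
        w = self.weights[idx]
        y = self.labels[idx]
        tw = w.sum()
        ta = (w * y).sum()
        if ta <= _TOL or tw - ta <= _TOL:  # pure subset: nothing to gain
            return np.zeros(X.shape[1])
        Xn = X[idx]
        pres_w = w @ Xn
        pres_a = (w * y) @ Xn
        abs_w = tw - pres_w
        abs_a = ta - pres_a
        p_pres = np.divide(pres_a, pres_w, out=np.zeros_like(pres_a), where=pres_w > 0)
        p_abs = np.divide(abs_a, abs_w, out=np.zeros_like(abs_a), where=abs_w > 0)
        h_pres = np.where(pres_w > 0, _entropy(p_pres), 0.0)
        h_abs = np.where(abs_w > 0, _entropy(p_abs), 0.0)
        gain = _entropy(ta / tw) - (pres_w * h_pres + abs_w * h_abs) / tw
        return np.where((pres_w > _TOL) & (abs_w > _TOL), gain, -np.inf)

    def _select_hypotheses(self, X: np.ndarray) -> list[Hypothesis]:
        cfg = self.config
        n, n_feat = X.shape
        if n_feat == 0:
            return []
        support_counts = X.sum(axis=0)
        eligible = support_counts >= cfg.min_support
        # hypothesis gains are reported on the whole training set so they are
        # comparable across selection depths
        global_gain = self._gain_vector(X, np.arange(n))
        found: dict[frozenset[int], Hypothesis] = {}

        def recurse(mask: np.ndarray, depth: int) -> None:
            idx = np.flatnonzero(mask)
            if depth >= cfg.max_depth or idx.size < max(2, cfg.min_support):
                return
            y = self.labels[idx]
            if y.all() or not y.any():  # pure node
                return
            gain = np.where(eligible, self._gain_vector(X, idx), -np.inf)
            gmax = gain.max()
            if not np.isfinite(gmax) or gmax <= _TOL:
                return
            ties = np.flatnonzero(gain >= gmax - _TOL)
            # deterministic tie-break: larger global support, then lexicographic code
            best = min(ties, key=lambda j: (-support_counts[j], self.vocab[j]))
            merged = [
                j for j in ties
                if support_counts[j] == support_counts[best] and np.array_equal(X[:, j], X[:, best])
            ]
            support = frozenset(np.flatnonzero(X[:, best]).tolist())
            hyp = Hypothesis(
                feature_codes=tuple(sorted(self.vocab[j] for j in merged)),
                support=support,
                gain=float(max(global_gain[best], 0.0)),
                depth=depth,
            )
            prev = found.get(support)
            if prev is None or depth < prev.depth:
                found[support] = hyp
            present = mask & X[:, best]
            absent = mask & ~X[:, best]
            recurse(present, depth + 1)
            recurse(absent, depth + 1)

        recurse(np.ones(n, dtype=bool), 0)
        hyps = sorted(found.values(), key=lambda h: (-h.gain, -len(h.support), h.key))
        if not hyps:
            logger.info("SOHN: no feature with positive gain; model will fall back to global kNN")
        return hyps

    # ---------------------------------------------------------- prediction

    def _require_fitted(self) -> None:
        if not self._fitted:
            raise RuntimeError("SohnModel is not trained; call fit() first")

    def _local_knn(
        self, support: Sequence[int], sims: np.ndarray
    ) -> tuple[Call, float, int]:
        cfg = self.config
        support = sorted(support)
        k = min(cfg.k, len(support))
        ranked = sorted(support, key=lambda i: (-sims[i], i))[:k]
        w = self.weights[ranked]
        labels = [Call.ACTIVE if self.labels[i] else Call.INACTIVE for i in ranked]
        active_w = w[[lab == Call.ACTIVE for lab in labels]].sum()
        # conservative tie: active wins at exactly half the vote weight
        call = Call.ACTIVE if active_w >= w.sum() / 2 else Call.INACTIVE
        conf = sohn_confidence(sims[ranked], labels, call, w)
        return call, conf, k

    def predict_record(self, record: MoleculeRecord) -> Prediction:
        self._require_fitted()
        mol = mol_from_record(record)
        return self._predict(mol, record.id)

    def predict(self, records: Sequence[MoleculeRecord]) -> list[Prediction]:
        return [self.predict_record(r) for r in records]

    def _predict(self, mol: Chem.Mol, rid: str) -> Prediction:
        cfg = self.config
        qset = {f.code for f in _feat.enumerate_atom_pairs(mol, cfg.d_min, cfg.d_max)}
        qfp = _feat.morgan_fingerprint(mol)
        sims = _feat.bulk_tanimoto(qfp, self.fps)
        applicable = applicable_hypotheses(self.network, qset)
        if not applicable:
            call, conf, k = self._local_knn(range(len(self.records)), sims)
            logger.debug("SOHN: %s out of domain; global %d-NN fallback", rid, k)
            return Prediction(rid, call, conf, "sohn", provenance="out_of_domain:global_knn")
        locals_: list[tuple[Call, float, Hypothesis]] = []
        for hyp in applicable:
            call, conf, _ = self._local_knn(hyp.support, sims)
            locals_.append((call, conf, hyp))
        if cfg.combine == "weighted_vote":
            active = sum(c for call, c, _ in locals_ if call == Call.ACTIVE)
            total = sum(c for _, c, _ in locals_)
            final = Call.ACTIVE if total == 0 or active >= total / 2 else Call.INACTIVE
            conf = active / total if final == Call.ACTIVE and total > 0 else (
                (total - active) / total if total > 0 else 0.0
            )
            prov = "vote:" + "|".join(h.key for _, _, h in locals_)
            return Prediction(rid, final, conf, "sohn", provenance=prov)
        # max-confidence combination; confidence ties resolved conservatively
        best = min(locals_, key=lambda t: (-t[1], 0 if t[0] == Call.ACTIVE else 1, t[2].key))
        call, conf, hyp = best
        return Prediction(rid, call, conf, "sohn", provenance=f"hypothesis:{hyp.key}")

    # --------------------------------------------------------- persistence

    def save(self, path: str | Path) -> None:
        self._require_fitted()
        joblib.dump(
            {
                "format": "hergml-sohn",
                "version": 1,
                "config": self.config,
                "records": self.records,
                "weights": self.weights,
                "hypotheses": self.hypotheses,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "SohnModel":
        payload = joblib.load(path)
        if payload.get("format") != "hergml-sohn":
            raise InputError(f"{path} is not a SOHN model archive")
        model = cls(payload["config"])
        model.fit(payload["records"], sample_weight=payload["weights"])
        return model


# ------------------------------------------------------- functional surface


def select_hypotheses(
    train: Sequence[MoleculeRecord],
    min_support: int = 5,
    max_depth: int = 10,
    seed: int = 0,
) -> list[Hypothesis]:
    """Select informative atom-pair hypotheses by recursive partitioning."""
    model = SohnModel(SohnConfig(min_support=min_support, max_depth=max_depth, seed=seed))
    model.fit(train)
    return model.hypotheses


def build_network(hyps: Sequence[Hypothesis]) -> HypothesisNetwork:
    """Arrange hypotheses into a Hasse diagram of strict support inclusion.

    Hypotheses with identical support are merged into a single node carrying
    all of their feature codes; edges are transitively reduced.
    """
    merged: dict[frozenset[int], Hypothesis] = {}
    for h in hyps:
        prev = merged.get(h.support)
        if prev is None:
            merged[h.support] = h
        else:
            merged[h.support] = Hypothesis(
                feature_codes=tuple(sorted(set(prev.feature_codes) | set(h.feature_codes))),
                support=h.support,
                gain=max(prev.gain, h.gain),
                depth=min(prev.depth, h.depth),
            )
    nodes = sorted(merged.values(), key=lambda h: (-len(h.support), h.key))
    n = len(nodes)
    subset = [[i != j and nodes[j].support < nodes[i].support for j in range(n)] for i in range(n)]
    children: dict[int, tuple[int, ...]] = {}
    for i in range(n):
        kids = []
        for j in range(n):
            if not subset[i][j]:
                continue
            # Hasse reduction: keep only covers (no intermediate node between)
            if not any(subset[i][m] and subset[m][j] for m in range(n)):
                kids.append(j)
        if kids:
            children[i] = tuple(kids)
    return HypothesisNetwork(nodes=nodes, children=children)


def applicable_hypotheses(net: HypothesisNetwork, query) -> list[Hypothesis]:
    """The most specific hypotheses applicable to a query.

    ``query`` is a molecule or a precomputed set of atom-pair codes. A
    hypothesis applies when the query contains (any of) its feature(s); only
    applicable hypotheses with no applicable descendant are returned.
    """
    if isinstance(query, Chem.Mol):
        qset = {f.code for f in _feat.enumerate_atom_pairs(query)}
    else:
        qset = {c.code if isinstance(c, AtomPairFeature) else str(c) for c in query}
    matching = [i for i, h in enumerate(net.nodes) if any(c in qset for c in h.feature_codes)]
    matching_set = set(matching)
    return [
        net.nodes[i]
        for i in matching
        if not (net.descendants(i) & matching_set)
    ]


def local_knn_predict(
    h: Hypothesis,
    query: Chem.Mol,
    k: int,
    train: Sequence[MoleculeRecord],
) -> tuple[Call, float]:
    """Evaluate one hypothesis as a local kNN model for a query molecule."""
    if not h.support:
        raise InputError("hypothesis has empty support")
    qfp = _feat.morgan_fingerprint(query)
    fps = [_feat.morgan_fingerprint(mol_from_record(train[i])) for i in sorted(h.support)]
    sims = _feat.bulk_tanimoto(qfp, fps)
    ranked = sorted(range(len(sims)), key=lambda i: (-sims[i], i))[: max(1, min(k, len(sims)))]
    labels = [train[i].call for i in sorted(h.support)]
    chosen = [labels[i] for i in ranked]
    n_active = sum(lab == Call.ACTIVE for lab in chosen)
    call = Call.ACTIVE if n_active >= len(chosen) / 2 else Call.INACTIVE
    return call, sohn_confidence(sims[ranked], chosen, call)
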