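"""Random-forest hERG classifier with a similarity-aware confidence score.

Features are the concatenation of a physicochemical descriptor panel with
plain and feature-invariant Morgan fingerprints (radius 4, 4096 bits each).
Every prediction carries a confidence score

    CS = (max Tanimoto similarity to the training set + forest probability
          of the predicted class) / 2,

the arithmetic mean of an applicability-domain term and the model's own
vote fraction. Both terms lie in [0, 1]; because the predicted-class
probability of a binary forest is at least 0.5, CS typically lies between
0.5 and 1, reaching 1 only for an exact training-set match predicted
unanimously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import features as _feat
from .chemio import Call, InputError, MoleculeRecord, Prediction, mol_from_record

logger = logging.getLogger(__name__)


@dataclass
class RfConfig:
    n_estimators: int = 500
    max_features: str | float = "sqrt"
    max_depth: int | None = None
    bootstrap: bool = True
    seed: int = 0


def confidence_score(max_similarity: float, model_probability: float) -> float:
    """Arithmetic mean of training-set similarity and predicted-class probability."""
    if not 0.0 <= max_similarity <= 1.0:
        raise InputError(f"max_similarity {max_similarity} outside [0, 1]")
    if not 0.0 <= model_probability <= 1.0:
        raise InputError(f"model_probability {model_probability} outside [0, 1]")
    return (max_similarity + model_probability) / 2.0


def featurize(mol) -> np.ndarray:
    """Descriptor block: physchem || Morgan(4, 4096) || feature-Morgan(4, 4096)."""
    return np.concatenate(
        [
            _feat.physchem_descriptors(mol),
            _feat.fingerprint_to_array(_feat.morgan_fingerprint(mol)),
            _feat.fingerprint_to_array(_feat.morgan_fingerprint(mol, feature_variant=True)),
        ]
    )


class RfModel:
    """Random forest over concatenated descriptor/fingerprint blocks."""

    def __init__(self, config: RfConfig | None = None):
        self.config = config or RfConfig()
        self._fitted = False

    def fit(
        self,
        records: Sequence[MoleculeRecord],
        sample_weight: Sequence[float] | None = None,
    ) -> "RfModel":
        if not records:
            raise InputError("cannot train on an empty dataset")
        if any(r.call is None for r in records):
            raise InputError("all training records need a binary call (curate first)")
        calls = {r.call for r in records}
        if len(calls) < 2:
            raise InputError("training set contains a single class; need both calls")
        # Sort-stabilise so the fit is invariant to input row order.
        order = sorted(range(len(records)), key=lambda i: (records[i].smiles, records[i].id))
        self.records = [records[i] for i in order]
        weight = None
        if sample_weight is not None:
            w = np.asarray(sample_weight, dtype=float)
            if w.shape != (len(records),) or (w < 0).any() or w.sum() <= 0:
                raise InputError("sample_weight must be non-negative with positive total")
            weight = w[order]
        mols = [mol_from_record(r) for r in self.records]
        X = np.stack([featurize(m) for m in mols])
        y = np.array([r.call == Call.ACTIVE for r in self.records], dtype=int)
        cfg = self.config
        self.forest = RandomForestClassifier(
            n_estimators=cfg.n_estimators,
            max_features=cfg.max_features,
            max_depth=cfg.max_depth,
            bootstrap=cfg.bootstrap,
            random_state=cfg.seed,
            n_jobs=1,
        )
        self.forest.fit(X, y, sample_weight=weight)
        # plain Morgan block retained for the similarity term of the confidence
        self.train_fps = [_feat.morgan_fingerprint(m) for m in mols]
        self._fitted = True
        return self

    def _require_fitted(self) -> None:
        if not self._fitted:
            raise RuntimeError("RfModel is not trained; call fit() first")

    def predict_record(self, record: MoleculeRecord) -> Prediction:
        return self.predict([record])[0]

    def predict(self, records: Sequence[MoleculeRecord]) -> list[Prediction]:
        self._require_fitted()
        if not records:
            return []
        mols = [mol_from_record(r) for r in records]
        X = np.stack([featurize(m) for m in mols])
        proba = self.forest.predict_proba(X)
        active_col = list(self.forest.classes_).index(1)
        out = []
        for record, mol, p in zip(records, mols, proba):
            active_p = p[active_col]
            call = Call.ACTIVE if active_p >= 0.5 else Call.INACTIVE
            model_probability = active_p if call == Call.ACTIVE else 1.0 - active_p
            qfp = _feat.morgan_fingerprint(mol)
            max_sim = float(_feat.bulk_tanimoto(qfp, self.train_fps).max())
            cs = confidence_score(max_sim, model_probability)
            out.append(
                Prediction(
                    record.id,
                    call,
                    cs,
                    "rf",
                    provenance=f"p={model_probability:.4f};max_sim={max_sim:.4f}",
                )
            )
        return out

    def predict_proba_active(self, records: Sequence[MoleculeRecord]) -> np.ndarray:
        """Forest probability of the active class (determinism checks, plots)."""
        self._require_fitted()
        X = np.stack([featurize(mol_from_record(r)) for r in records])
        proba = self.forest.predict_proba(X)
        return proba[:, list(self.forest.classes_).index(1)]

    def save(self, path: str | Path) -> None:
        self._require_fitted()
        joblib.dump(
            {
                "format": "hergml-rf",
                "version": 1,
                "config": self.config,
                "forest": self.forest,
                "records": self.records,
                "train_fps_smiles": [r.smiles for r in self.records],
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "RfModel":
        payload = joblib.load(path)
        if payload.get("format") != "hergml-rf":
            raise InputError(f"{path} is not an RF model archive")
        model = cls(payload["config"])
        model.forest = payload["forest"]
        model.records = payload["records"]
        from rdkit import Chem

        model.train_fps = [
            _feat.morgan_fingerprint(Chem.MolFromSmiles(s)) for s in payload["train_fps_smiles"]
        ]
        model._fitted = True
        return model


def train_rf(
    train: Sequence[MoleculeRecord],
    config: RfConfig | None = None,
    seed: int | None = None,
    sample_weight: Sequence[float] | None = None,
) -> RfModel:
    cfg = config or RfConfig()
    if seed is not None:
        cfg = RfConfig(cfg.n_estimators, cfg.max_features, cfg.max_depth, cfg.bootstrap, seed)
    return RfModel(cfg).fit(train, sample_weight=sample_weight)


def predict_rf(model: RfModel, query: MoleculeRecord) -> Prediction:
    return model.predict_record(query)
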