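"""Shared fixtures: small synthetic datasets and the cached 10-seed benchmark."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hergml.ensemble import run_benchmark
from hergml.sohn import SohnConfig, SohnModel
from hergml.synthetic import (
    PlantedMotif,
    SimulationConfig,
    generate_dataset,
    motif_signature_features,
    with_seed,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-source dataset for fast model-level tests."""
    cfg = SimulationConfig(n_public=120, n_private_train=120, n_private_test=60)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def benchmark10():
    """The default synthetic benchmark over ten seeds (shared: it is slow)."""
    return run_benchmark(seeds=list(range(10)))


SINGLE_MOTIF = PlantedMotif("dimethylaminoethyl", "CCN(C)C", 0, 2.5, 0.4, 0.4, 0.4)

RECOVERY_CONFIG = SimulationConfig(
    n_public=10,
    n_private_train=400,
    n_private_test=10,
    motifs=(SINGLE_MOTIF,),
    label_flip_private=0.1,
    scaffold_effect_sd=0.0,
)


@pytest.fixture(scope="session")
def recovery_hits():
    """Seeds (of 20) where the planted atom pair ranks in the top-3 hypotheses."""
    signature = {f.code for f in motif_signature_features(SINGLE_MOTIF)}
    hits = 0
    for seed in range(20):
        data = generate_dataset(with_seed(RECOVERY_CONFIG, seed))
        model = SohnModel(SohnConfig(seed=seed)).fit(data.private_train)
        top3 = sorted(model.hypotheses, key=lambda h: -h.gain)[:3]
        hits += any(set(h.feature_codes) & signature for h in top3)
    return hits
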