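"""Model and data-source combination strategies.

Three mechanisms, composable:

* **Source weighting** — train one model on public and private data jointly,
  with per-record sample weights arranged so the two sources' total
  effective weights stand in a configured a:b ratio (5:0 and 0:5 degenerate
  to single-source models).
* **Expert fallback** — trust the statistical model while its per-prediction
  confidence is at least a threshold tau; below it, defer to the
  structural-alert expert.
* **Most-confident consensus** — among several statistical predictions,
  keep the call of the model reporting the highest confidence.

The full stack applies the consensus of the two statistical models first
and falls back to the expert when even the consensus confidence is below
tau (default 0.7). Statistical confidences are assumed mutually comparable;
no calibration is applied. Confidence ties with conflicting calls resolve
conservatively to active.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as _dc_replace
from typing import Sequence

import numpy as np
import pandas as pd

from .alerts import StructuralAlert, default_alerts, expert_predict
from .chemio import Call, ConfigurationError, InputError, MoleculeRecord, Prediction
from .evalmetrics import ConfusionMetrics, confusion
from .rf_model import RfConfig, RfModel
from .sohn import SohnConfig, SohnModel
from .synthetic import SimulationConfig, SyntheticDataset, generate_dataset, with_seed

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SourceRatio:
    """Relative total training influence of public vs private data (a:b)."""

    public_weight: float
    private_weight: float

    def __post_init__(self) -> None:
        if self.public_weight < 0 or self.private_weight < 0:
            raise ConfigurationError("ratio weights must be non-negative")
        if self.public_weight == 0 and self.private_weight == 0:
            raise ConfigurationError("ratio weights cannot both be zero")

    @classmethod
    def parse(cls, text: str) -> "SourceRatio":
        a, _, b = text.partition(":")
        return cls(float(a), float(b))

    def __str__(self) -> str:
        def fmt(x: float) -> str:
            return str(int(x)) if float(x).is_integer() else str(x)

        return f"{fmt(self.public_weight)}:{fmt(self.private_weight)}"


def weighted_training_set(
    public: Sequence[MoleculeRecord],
    private: Sequence[MoleculeRecord],
    ratio: SourceRatio,
) -> tuple[list[MoleculeRecord], np.ndarray | None]:
    """Concatenate the sources with per-record weights in ratio a:b.

    Each source's records share its total effective weight equally, so the
    a:b ratio holds regardless of the sources' sizes. A zero-weight source
    is dropped entirely and uniform (``None``) weights are returned, making
    5:0 / 0:5 exactly the single-source training inputs.
    """
    if ratio.private_weight == 0:
        if not public:
            raise InputError("ratio excludes private data but public set is empty")
        return list(public), None
    if ratio.public_weight == 0:
        if not private:
            raise InputError("ratio excludes public data but private set is empty")
        return list(private), None
    if not public or not private:
        raise InputError("both sources must be non-empty for a mixed ratio")
    records = [*public, *private]
    w_pub = ratio.public_weight / len(public)
    w_priv = ratio.private_weight / len(private)
    weights = np.array([w_pub] * len(public) + [w_priv] * len(private))
    weights *= len(records) / weights.sum()  # mean weight 1, pure rescaling
    return records, weights


def combine_fallback(stat: Prediction, expert: Prediction, tau: float) -> Prediction:
    """Keep the statistical call at confidence >= tau, else the expert's."""
    if stat.confidence is None:
        raise InputError("fallback combination needs a numeric statistical confidence")
    if stat.confidence >= tau:
        return stat
    return Prediction(
        id=stat.id,
        call=expert.call,
        confidence=stat.confidence,
        model=f"{stat.model}+expert",
        provenance=f"fallback(conf={stat.confidence:.4f}<{tau:g}):{expert.provenance}",
    )


def combine_most_confident(preds: Sequence[Prediction]) -> Prediction:
    """The prediction of the most confident model; active wins exact ties."""
    numeric = [p for p in preds if p.confidence is not None]
    if not numeric:
        raise InputError("need at least one prediction with a numeric confidence")
    best_conf = max(p.confidence for p in numeric)
    tied = [p for p in numeric if p.confidence == best_conf]
    calls = {p.call for p in tied}
    if len(calls) > 1:
        logger.debug("confidence tie with conflicting calls for %s; keeping active", tied[0].id)
    # permutation-invariant: prefer active on a tie, then stable on model name
    return min(tied, key=lambda p: (0 if p.call == Call.ACTIVE else 1, p.model))


def full_stack_predict(
    sohn_model: SohnModel,
    rf_model: RfModel,
    alerts: Sequence[StructuralAlert],
    query: MoleculeRecord,
    tau: float = 0.7,
) -> Prediction:
    """Consensus of SOHN and RF, with the expert as a low-confidence fallback."""
    stat = combine_most_confident(
        [sohn_model.predict_record(query), rf_model.predict_record(query)]
    )
    expert = expert_predict(alerts, query)
    combined = combine_fallback(stat, expert, tau)
    return _dc_replace(
        combined, model="full_stack", provenance=f"{stat.model}:{combined.provenance}"
    )


# --------------------------------------------------------------- benchmark


DEFAULT_RATIOS: tuple[str, ...] = ("5:0", "0:5", "2:5")


@dataclass
class BenchmarkResult:
    """Tidy per-(seed, model) metrics plus the raw per-seed predictions."""

    table: pd.DataFrame

    def mean_metric(self, model: str, metric: str = "MCC") -> float:
        rows = self.table[self.table["model"] == model]
        if rows.empty:
            raise InputError(f"no benchmark rows for model {model!r}")
        return float(rows[metric].mean())

    def models(self) -> list[str]:
        return sorted(self.table["model"].unique())


def _metric_row(name: str, seed: int, experiment: str, m: ConfusionMetrics) -> dict:
    return {"seed": seed, "experiment": experiment, "model": name, **m.as_row(), "n": m.n}


def run_benchmark(
    cfg: SimulationConfig | None = None,
    seeds: Sequence[int] = (0,),
    tau: float = 0.7,
    tau_grid: Sequence[float] = (0.6, 0.7, 0.8),
    rf_config: RfConfig | None = None,
    sohn_config: SohnConfig | None = None,
    alerts: Sequence[StructuralAlert] | None = None,
) -> BenchmarkResult:
    """Run the five combination experiments on synthetic data.

    Per seed: generate the two-source datasets, train RF and SOHN on public
    only (5:0), private only (0:5) and the mixed 2:5 weighting, score the
    expert surrogate, and evaluate every individual model plus the fallback,
    consensus and full-stack combinations on the late-period test set.
    """
    cfg = cfg or SimulationConfig()
    alerts = list(alerts) if alerts is not None else default_alerts()
    rows: list[dict] = []
    for seed in seeds:
        data = generate_dataset(with_seed(cfg, seed))
        test = data.private_test
        truth = [r.call for r in test]

        def ev(name: str, experiment: str, preds: Sequence[Prediction]) -> None:
            m = confusion([p.call for p in preds], truth)
            rows.append(_metric_row(name, seed, experiment, m))

        expert_preds = [expert_predict(alerts, r) for r in test]
        ev("expert", "exp1", expert_preds)

        preds: dict[tuple[str, str], list[Prediction]] = {}
        models: dict[tuple[str, str], object] = {}
        for ratio_text in ("5:0", "0:5", "2:5"):
            ratio = SourceRatio.parse(ratio_text)
            records, weights = weighted_training_set(data.public, data.private_train, ratio)
            rf = RfModel(rf_config or RfConfig(seed=seed)).fit(records, sample_weight=weights)
            sohn = SohnModel(sohn_config or SohnConfig(seed=seed)).fit(records, sample_weight=weights)
            models[("rf", ratio_text)] = rf
            models[("sohn", ratio_text)] = sohn
            preds[("rf", ratio_text)] = rf.predict(test)
            preds[("sohn", ratio_text)] = sohn.predict(test)

        name_for = {"5:0": "public", "0:5": "private", "2:5": "mixed_2to5"}
        for (model, ratio_text), p in preds.items():
            experiment = "exp1" if ratio_text in ("5:0", "0:5") else "exp2"
            ev(f"{model}_{name_for[ratio_text]}", experiment, p)

        # expert fallback on the private-trained models, over a tau grid
        for t in tau_grid:
            for model in ("rf", "sohn"):
                combined = [
                    combine_fallback(s, e, t)
                    for s, e in zip(preds[(model, "0:5")], expert_preds)
                ]
                ev(f"{model}_private_expert_tau{t:g}", "exp3", combined)

        consensus = [
            combine_most_confident([s, r])
            for s, r in zip(preds[("sohn", "2:5")], preds[("rf", "2:5")])
        ]
        ev("consensus_mixed_2to5", "exp4", consensus)

        full = [
            combine_fallback(c, e, tau) for c, e in zip(consensus, expert_preds)
        ]
        ev("full_stack_mixed_2to5", "exp5", full)
    return BenchmarkResult(table=pd.DataFrame(rows))


def summarize_benchmark(result: BenchmarkResult) -> pd.DataFrame:
    """Mean metrics over seeds, one row per model, in experiment order."""
    table = result.table
    grouped = (
        table.groupby(["experiment", "model"], sort=True)
        .mean(numeric_only=True)
        .drop(columns=["seed"])
        .reset_index()
    )
    return grouped
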