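# hergml

Tools for predicting hERG channel liability from chemical structure, and
for studying how statistical models, expert structural alerts, and
public/private training data combine into better predictors.

Blockade of the hERG potassium channel prolongs the cardiac QT interval
and can cause torsades de pointes, so candidate compounds are screened
in silico long before patch-clamp assays. This package implements the
full screening stack at desk scale:

* **SOHN** — a self-organising hypothesis network: typed atom pairs
  (element + aromaticity + hybridisation + bonded-neighbour environment,
  at 2–20 bond topological distance) act as toxicophoric hypotheses,
  selected by recursive partitioning on information gain, organised into a
  Hasse hierarchy by support-set inclusion, and evaluated as local
  k-nearest-neighbour models with a similarity/agreement confidence.
* **RF** — a random forest over physicochemical descriptors plus plain and
  feature Morgan fingerprints (radius 4, 4096 bits), with per-prediction
  confidence
  `CS = (max similarity to training data + model probability) / 2`.
* **Expert surrogate** — SMARTS structural alerts (training-free,
  categorical matched/no-match confidence).
* **Ensembles** — public:private sample weighting (a:b ratios),
  confidence-threshold fallback to the expert, and most-confident-model
  consensus.
* **Curation** — threshold harmonisation (active below 10 µM potency, above
  50 % inhibition at 10 µM), conservative call merging, replicate
  averaging, and temporal train/test splitting.
* **Synthetic benchmark** — a molecule generator that plants toxicophoric
  motifs into scaffold/decoration chemistry and emulates a broad noisy
  public source, a narrow clean private source, and a negatively biased
  (75 % inactive) late-period test set.

## Worked example

```python
from hergml import (
    RfConfig, RfModel, SohnConfig, SohnModel, SimulationConfig,
    confusion, generate_dataset, metrics_table,
)

data = generate_dataset(SimulationConfig(seed=0))
rf = RfModel(RfConfig(seed=0)).fit(data.private_train)
sohn = SohnModel(SohnConfig(seed=0)).fit(data.private_train)

truth = [r.call for r in data.private_test]
rows = {
    "RF_private": confusion([p.call for p in rf.predict(data.private_test)], truth),
    "SOHN_private": confusion([p.call for p in sohn.predict(data.private_test)], truth),
}
print(metrics_table(rows))
```

```
               ACC    BA  SENS  SPEC   PPV   NPV   MCC  KAPPA
model
RF_private    0.72  0.73  0.75  0.70  0.46  0.89  0.40   0.37
SOHN_private  0.67  0.68  0.71  0.66  0.41  0.87  0.32   0.29
```

Reading the row: on the 316-compound late-period test set (75 % inactive),
the private-trained forest recovers 75 % of the observed channel blockers
(SENS) while keeping 70 % specificity; MCC and Cohen's kappa are the
imbalance-robust summary statistics. Per-prediction confidences drive the
ensembles:

```python
from hergml import combine_most_confident, default_alerts, full_stack_predict

query = data.private_test[0]
consensus = combine_most_confident([rf.predict_record(query), sohn.predict_record(query)])
stacked = full_stack_predict(sohn, rf, default_alerts(), query, tau=0.7)
```

The same pipeline is scriptable: `hergml simulate`, `curate`, `train`,
`predict`, `alerts-predict`, `evaluate` and `hergml experiment` (the whole
five-experiment comparison, emitting per-seed and summary metric tables as
CSV). See `hergml --help`.

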