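# Methods

## Problem setting

hERG (Kv11.1) channel blockade is assessed as a binary classification
problem: a compound is *active* (a liability) or *inactive*. Training data
come from two kinds of sources with very different properties. Public
bioactivity collections are broad but heterogeneous: they mix IC50/EC50/Ki
potencies, single-concentration inhibition screens and qualitative author
calls measured under many protocols, which injects label noise. Corporate
(private) screens are narrow but clean: a single protocol, a focused
chemical series, low noise. Evaluation is prospective: models are tested on
compounds registered *after* everything they were trained on, and because
medicinal chemists design away from known liabilities, such late-period
test sets are strongly negatively biased (here 75 % inactive) and their
remaining actives tend to carry unexpected structural triggers.

## Curation model

Raw measurements are reduced to calls under a `ThresholdPolicy`:

* potencies (IC50, EC50, Ki, µM): active strictly below 10 µM (Ki and EC50
  use the same 10 µM-equivalent cutoff by default; per-kind overrides are
  configuration, not constants, because no principled conversion is
  available);
* percent inhibition at 10 µM: active strictly above 50 %;
* author calls: trusted verbatim.

Values exactly on a threshold are inactive (the strict-inequality boundary
is a documented convention; the choice matters only for values printed at
the cutoff). Replicated inhibition screens are averaged *before*
binarisation; all other per-compound calls merge conservatively (one active
call ⇒ active). These two reductions do not commute — inhibitions
[20 %, 60 %] average to inactive but call-merge to active — and the mean-
first rule is the one used for replicated single-protocol screens; a
regression test pins the difference. Temporal splits assign records dated
on/before the cutoff to training, later records to test, exclude undated
records with a warning, and drop from the test side any canonical structure
already present in training so no compound appears in both sets.

## Features

* **Typed atom pairs** (the SOHN representation). Each heavy atom gets the
  code `element.environment[sorted bonded heavy elements]`, where
  environment is `ar` for aromatic atoms and the hybridisation otherwise
  (e.g. `N.sp3[CCC]`). This is an environment-refined typing in the spirit
  of extended Ghose–Crippen atom types; formal charge is deliberately not
  distinguished (a documented approximation). A feature is an unordered
  typed pair plus the shortest topological bond distance, kept for
  distances 2–20. A brute-force BFS oracle checks the enumeration.
* **Morgan fingerprints**, radius 4, 4096 bits, plain and
  feature-invariant variants.
* **Physicochemical descriptors**: a fixed panel of 40 standard 2D RDKit
  descriptors (molecular weight, logP, TPSA, ring/H-bond counts, kappa
  shapes, etc.; the exact list is `PHYSCHEM_DESCRIPTOR_NAMES` and is
  configurable). Non-finite values are imputed to 0 with a warning.
* **Similarity** is Tanimoto on the plain radius-4/4096 Morgan
  fingerprint everywhere a similarity is needed (SOHN neighbourhoods and
  the RF confidence). Two empty fingerprints are defined to have
  similarity 0.

## SOHN

Hypothesis selection is recursive partitioning: at each node, the
atom-pair feature with the highest weighted Shannon information gain over
the node's compounds splits them into present/absent; recursion stops at
purity, `max_depth` (8), or nodes smaller than `min_support` (10). Only
features supported by at least `min_support` training compounds are
eligible. Gain ties break deterministically (larger global support, then
lexicographic feature code), and tied features with *identical* support
are merged into a single hypothesis — atom pairs internal to one rigid
motif are indistinguishable on the training data and are treated as one
toxicophoric hypothesis. Each selected hypothesis is reported with its
global support set and its information gain computed on the full training
set, so gains are comparable across selection depths; an exhaustive
plain-Python gain scan serves as the oracle for the root split.

The hypotheses form a Hasse diagram under strict support inclusion
(transitively reduced; equal supports merged). For a query, the most
specific applicable hypotheses (feature present in the query, no
applicable descendant) each act as a local kNN model: the `k = 9` nearest
supporting compounds by Tanimoto vote with their sample weights, exact
half-splits resolving conservatively to active. Local confidence is

    confidence = mean(similarity) × fraction agreeing with the call,

overridden to exactly 1 when the query matches a training structure
(max similarity 1) or the neighbourhood is unanimous. These two anchor
conditions are fixed points of the design; the product form between them
is an interpolation chosen for monotonicity in both factors. The final
call is the most confident local prediction (conflicting ties → active);
a weighted-vote combination mode is available behind `SohnConfig.combine`.
Queries matching no hypothesis fall back to a global kNN over the whole
training set and are flagged out-of-domain in the provenance.

Defaults (`min_support=10, max_depth=8, k=9`) were set where the
confidence is informative rather than saturated: with very small
neighbourhoods the unanimity anchor fires on a large fraction of
predictions, which both inflates false positives (through the conservative
tie) and defeats confidence arbitration in the ensembles. All three are
configuration, and nothing in the method depends on the specific values.

## Random forest

500 trees, √-features per split, unlimited depth, bootstrap resampling
(all configurable; sample weights are honoured by the resampling). The
feature block is `physchem ‖ Morgan ‖ feature-Morgan`. Training sorts
records by (canonical SMILES, id) so fits are invariant to input row
order at a fixed seed. Confidence is

    CS = (max Tanimoto to training set + P(predicted class)) / 2,

an applicability-domain term averaged with the forest's own vote
fraction. The probability term is that of the *predicted* class, hence
≥ 0.5 for a binary forest, which is why CS typically lies in [0.5, 1].
The similarity term uses the plain Morgan block only.

## Expert surrogate

A training-free structural-alert matcher over a TSV of SMARTS patterns.
The bundled five-alert set encodes variations of the classic hERG
pharmacophore (a basic amine within a few rotatable bonds of an aromatic
or lipophilic anchor). It is a synthetic surrogate written for this
package's benchmarks — a stand-in with the *shape* of an expert system
(high precision inside a narrow structural scope, categorical
matched/no-match confidence), not a reproduction of any proprietary
knowledge base, and its absolute performance is not comparable to any
published expert-system figure.

## Ensembles

* **Source weighting**: public and private records are concatenated with
  per-record weights such that the sources' total effective weights stand
  in the configured a:b ratio, each source sharing its total equally
  (weights are rescaled to mean 1; a zero-weight source is dropped so 5:0
  and 0:5 are *exactly* the single-source training inputs). Weighting was
  chosen over replication/subsampling because it is deterministic and
  realises exact ratios; the forest's weighted bootstrap gives the
  resampling interpretation at fixed seed.
* **Fallback**: keep the statistical call when its confidence ≥ τ, else
  defer to the expert; τ = 0 reproduces the statistical model, τ > 1 the
  expert. Default τ = 0.7.
* **Most-confident consensus**: the call of the model reporting the
  highest confidence; exact conflicting ties resolve to active
  (consistent with the conservative curation philosophy). SOHN and RF
  confidences are treated as comparable — an assumption, not a
  calibration; no Platt/isotonic scaling is applied anywhere.
* **Full stack**: consensus of the two statistical models, with the
  expert as fallback when even the consensus confidence is below τ.

## Synthetic benchmark

The generator assembles molecules by splicing decoration fragments onto a
30-scaffold library (fragments attach only at carbons, and motifs are
spliced last so nothing decorates a motif atom and changes its typed
environment). Activity follows a logistic mechanism:

    logit = base + Σ motif effects + scaffold-series effect

with `base = −1.5`, motif effects +2.5, and per-scaffold baseline effects
drawn once per dataset from N(0, 1.5²). The scaffold term encodes
series-dependent activity baselines; without it, motif knowledge would
transfer perfectly across chemical space and the public/private domain
distinction the benchmark exists to study would be vacuous. True labels
are Bernoulli in this probability; observed labels flip at 0.15 (public)
vs 0.05 (private), encoding protocol heterogeneity vs a single clean
assay.

Two motifs are planted. The *known* pharmacophore (a dimethylaminoethyl
basic amine) is equally prevalent everywhere (0.35). The *unexpected*
trigger (a phenylthioethyl group, structurally unrelated to the amine
pharmacophore and invisible to the alert surrogate) is common in public
data (0.30) and in the late test period (0.30) but essentially absent
from the private training window (0.01) — the "unexpected actives" that
only public data can teach. Private data use only the first 8 (core)
scaffolds; public molecules draw a core scaffold with probability 0.10
(`scaffold_overlap`) and a peripheral one otherwise.

Problem sizes are desk-scale by design: 900 public, 400 private-training
and 316 test compounds; the test set is composed by quota to be exactly
75 % observed-inactive, with dates in the post-split window. Each dataset
is deduplicated by canonical SMILES, and private train/test share no
structure. A master seed spawns independent substreams (mechanism, public,
private-train, test), so every dataset is independently reproducible.

What the generator does *not* emulate: real assay value distributions,
activity cliffs, stereochemistry, measured-value censoring, or the true
chemistry of any corporate collection. Passing benchmarks here demonstrate
that the algorithms recover planted structure under the stated noise and
shift — not any particular level of performance on real hERG data.

## Benchmark harness and observed behaviour

`run_benchmark` trains RF and SOHN on 5:0 (public-only), 0:5
(private-only) and 2:5 weightings per seed, evaluates the expert, the
fallback over τ ∈ {0.6, 0.7, 0.8} on the private models, the 2:5
consensus, and the full stack, always on the same late-period test set.
The acceptance script reports three-replicate means; the test suite uses
ten seeds.

Two honest observations. First, expert fallback barely helps (and can
hurt) here: the surrogate's precision is much lower than a curated expert
system's, and synthetic chemical space keeps Tanimoto similarities — and
hence RF confidences — low, so at τ = 0.7 the fallback fires on most
predictions. Second, the full stack inherits the same effect. The
combinations that the benchmark does reproduce robustly are the data-source
ordering (public < private ≤ mixed in mean MCC for both model families)
and the no-harm property of most-confident consensus.

## Numerical conventions

Degenerate metric denominators report 0 with an explicit flag rather than
NaN. Metric tables round half-to-even at 2 decimals for display; all
internal comparisons use full precision. Every stochastic operation takes
an explicit integer seed (default 0); hypothesis selection, network
construction and both predictors are bit-deterministic given (data,
weights, config, seed).
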