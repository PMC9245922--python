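# Methods

## Model

`varitol` treats variant interpretation as binary classification with a
reject option. The base learner is LightGBM with library-default
hyperparameters (100 trees, 31 leaves, learning rate 0.1); defaults are
deliberate — the boosted ensemble is robust to them and a fixed
configuration keeps results reproducible. The published ensemble consists
of B = 100 members, each trained on a bootstrap resample (with
replacement, same size as the training set); member *i*'s resample and
learner seed derive from `seed + i`, so retraining is bit-reproducible.

The spread of member probabilities is the model's uncertainty estimate.
Because the sampling distribution of the bootstrap probability is
unknown, the abstention band uses Chebyshev's inequality, which holds for
any distribution: μ ± kσ with k = √(1/(1−c)) covers at least a fraction c
of the distribution. The default confidence c = 0.95 gives k = √20 ≈
4.472. The 0.5 test is endpoint-inclusive: a band that touches 0.5
(including the degenerate case μ = 0.5, σ = 0) yields UV, the
conservative choice at the boundary. Chebyshev is loose for
near-Gaussian member spreads, so the band over-abstains rather than
over-calls — the intended failure direction for a clinical-style tool.

## Leakage control

Protein-level features (annotation log-odds, conservation profiles,
length) make variant-level random splits optimistic. All partitioning is
therefore by protein: the train/test split assigns whole proteins, and
CV fold assignment places shuffled proteins, in descending variant
count, onto the currently lightest fold (greedy bin packing — the
grouping mechanism is otherwise unconstrained, and this keeps fold sizes
even under skewed per-protein variant counts). Term-frequency tables for
LR/FS are built strictly from training variants; a dedicated test
asserts that annotations of out-of-training proteins cannot alter them.

Class balancing is exact 1:1 by seeded undersampling of the majority
class. Undersampling was chosen over oversampling because duplicated
variants would recur across bootstrap resamples and silently couple
ensemble members.

## Features

* **Propensity deltas.** One feature per complete AAindex scale (a scale
  missing any of the 20 values is dropped at load time), value
  `scale[ref] − scale[alt]`. The full AAindex release yields 617 complete
  scales; the synthetic benchmark ships 40 (see below).
* **Variation type.** 400 + 36 indicators. The 20-letter ordering is
  alphabetical by one-letter code; the six classes are hydrophobic
  (V,I,L,F,M,W,Y,C), negatively charged (D,E), positively charged
  (R,K,H), conformational (G,P), polar (N,Q,S), other (A,T).
* **Neighborhood.** Window of 23 positions — 11 each side plus the
  center (reference) residue — truncated at sequence ends. The five
  group frequencies use nonpolar {A,V,L,I,P,F,M,W,G}, polar
  {S,T,C,Y,N,Q}, charged {D,E,K,R,H}, positive {K,R,H}, negative {D,E};
  charged overlaps positive ∪ negative, so the frequencies are not a
  partition. Frequencies divide by the realized (truncated) window size,
  so they stay in [0,1] at the termini.
* **Conservation.** The substitution-tolerance score is computed from a
  user-supplied MSA rather than by running an external search-and-score
  pipeline: column probabilities are `(count + 0.1) / (depth + 2)` with
  gaps excluded and the query row included, and the score is
  p(alt)/max p(·). This is the core of a SIFT-style score without
  sequence weighting or Dirichlet-mixture pseudocounts; externally
  computed SIFT 4G scores can be passed in as a TSV and take precedence.
  The homolog count is MSA rows − 1, with a hits-count override
  accepted.
* **Protein features.** Three: length, first-residue flag, position.
  (Published feature tallies are ambiguous between one and three
  protein-derived quantities; all three are implemented, and the total
  with a full AAindex release is 617 + 436 + 25 + 2 + 3 + 1 + 1 = 1,085.)
* **LR / FS.** Natural log of the +1-smoothed ratio of per-class protein
  counts, summed over the protein's closed (GO) or raw (site) term set.
  The log base only rescales a feature seen by tree learners, but it is
  fixed (ln) for reproducibility. Raw counts are used without
  class-size normalization, matching the formula as printed (the +1
  smoothing is only meaningful on counts); a protein carrying both
  pathogenic and benign training variants contributes to both class
  tallies. An unannotated protein gets value 0 with an availability flag
  of false, and prediction routes to the without-GO model.

Feature ordering is fixed and embedded in saved models; loading verifies
a checksum over names and training metadata.

## Recursive feature elimination

Each round fits a single learner, ranks features by total split gain
(the tree-ensemble analog of "absolute weight"), and removes the bottom
10% (at least one feature), clamped so that target counts {100, 50, 20,
10} are hit exactly; snapshots are nested by construction. Final
predictors are trained on the 20-feature snapshot, separately for the
with-GO feature set and for the set with `go:lr`/`site:fs` removed. RFE
uses the same learner as the final model.

## Synthetic benchmark

The generator emulates the three structural assumptions the features
encode: pathogenic substitutions sit at conserved alignment columns, make
large hydropathy jumps, and occur in proteins whose annotations come
from a disease-skewed term pool. Each effect parameter is a mixing
weight: with probability equal to the effect the class-informative rule
applies, otherwise the draw is class-blind, so zeroing every effect
yields a null benchmark whose labels are provably independent of all
features. Defaults are the strong-signal study conditions: 300 proteins,
mean length 250 (Poisson, floor 40), 6 variants per protein, pathogenic
fraction 0.5 (exact by construction), conservation effect 0.9, delta
effect 0.8, GO skew 0.8, MSA depth 25, 35% of positions conserved, 10%
of proteins unannotated (exercising two-mode routing). Under the mixture
scheme the expected fraction of pathogenic variants at conserved columns
is e + (1−e)·0.35 (0.935 at e = 0.9), and tests check this analytic
value.

Sequences are uniform over the 20 residues; compositional realism is
irrelevant to the mechanics under test. The scale set is the
Kyte–Doolittle hydropathy index (the axis the delta effect uses) plus 39
standard-normal synthetic scales, written in AAindex1 flat format. The
ontology is a three-level DAG with occasional double parents so ancestor
closure is genuinely exercised. All randomness flows from one master
seed through named `SeedSequence` child streams.

What passing the synthetic recovery test does **not** show: performance
on real data, where conservation scores come from true homolog searches,
annotation skew is weaker and confounded with study bias, class balance
is artificial, and organism composition is highly skewed. The benchmark
validates the machinery (leakage-free splitting, feature computation,
abstention calibration, selection), not the biology.

## Problem sizes and numerical choices

The end-to-end recovery experiment uses the 300-protein default (1,800
variants, ~530 features with the 40-scale set, B = 100); the null
calibration uses 334 proteins (2,004 variants) with a 50% held-out
fraction — the larger test half tightens the Monte-Carlo standard error
of the AUC, and under the null nothing is lost by training on less — and
B = 20 with selection skipped, since abstention and selection do not
affect the forced-probability AUC being calibrated. Null-model AUC is
assessed on **all** held-out predictions: restricting to covered cases
conditions on the ensemble's overconfident noise fits and biases the
estimate away from 0.5.

Metric edge cases: any ratio with a zero denominator is reported as an
explicit undefined flag (`None`), never coerced to 0; MCC is undefined
when any confusion marginal is zero; OPM is undefined if any constituent
is. Forced (no-rejection) calls break the exact μ = 0.5 tie toward
benign. AUC uses mid-rank tie handling. Reports round to 3 decimals for
display only.

## Limitations

* The MSA-based conservation score is a documented stand-in
  interoperable with SIFT 4G output, not a reimplementation of SIFT 4G;
  database choice and search parameters of a real pipeline dominate its
  behavior and are upstream of this package.
* With B bootstrap members trained on the same sample, σ estimates
  bootstrap variability, not epistemic uncertainty in any formal sense;
  Chebyshev guarantees are about the member distribution itself.
* The published predictors were trained on curated human/animal/plant
  variant collections that require external downloads; this package
  reproduces the method and its evaluation arithmetic, not the trained
  model or its exact selected features.
* VCF input and genome-coordinate mapping are out of scope; input is
  protein-level (sequence + substitution).
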