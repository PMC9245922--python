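# varitol

Pathogenicity/tolerance prediction for single amino acid substitutions in
proteins from any organism, with a distribution-free reject option.

Most missense variants found in clinical or agricultural sequencing have no
experimental characterization, and interpretation tools are often restricted
to human proteins. `varitol` implements a species-agnostic predictor: for a
substitution such as `E41K` in a given protein it emits one of three calls —
**pathogenic**, **benign**, or **UV** (unclassified variant) when the model's
own uncertainty overlaps the decision boundary and an honest tool should
abstain.

## Method

Each substitution is described by up to 1,085 features in six families:

* **amino acid propensity deltas** — for every complete AAindex scale
  (hydropathy, volume, flexibility, …), `scale[ref] − scale[alt]`;
* **variation type** — a one-hot over the 20×20 ordered (ref, alt) residue
  pairs plus a one-hot over the 6×6 ordered pairs of physicochemical classes
  (hydrophobic V,I,L,F,M,W,Y,C; negatively charged D,E; positively charged
  R,K,H; conformational G,P; polar N,Q,S; other A,T);
* **neighborhood composition** — 20 residue counts and 5 group frequencies in
  a 23-residue window centered on the site;
* **evolutionary conservation** — the number of homologs and a SIFT-style
  tolerance score from a multiple sequence alignment: the pseudocount-smoothed
  probability of the alternate residue in the aligned column, normalized by
  the most frequent residue's probability (precomputed SIFT 4G scores can be
  supplied instead);
* **protein features** — sequence length, first-residue flag, variant
  position;
* **annotation log-odds** — per protein, `LR = Σᵢ ln((f(Pᵢ)+1)/(f(Nᵢ)+1))`
  over its GO terms after ancestor closure over the ontology DAG, where
  `f(Pᵢ)` and `f(Nᵢ)` count the pathogenic- and neutral-class training
  proteins carrying term *i*; `FS` is the same statistic over functional-site
  terms.

The classifier is an ensemble of *B* = 100 gradient-boosted tree models
(LightGBM), each fit on a bootstrap resample of the balanced (1:1) training
set. All data partitioning is **protein-disjoint**: every variant of a
protein falls on the same side of any split, so protein-level features cannot
leak. Member probabilities give a mean μ and standard deviation σ per
variant; by Chebyshev's inequality at least 1 − 1/k² of any distribution lies
within k standard deviations of its mean, so with k = √(1/(1−0.95)) = √20 the
band μ ± kσ is a 95% distribution-free confidence interval. If the band
contains 0.5 the call is UV; otherwise the class follows the side of 0.5.
Recursive feature elimination (fit, rank by split gain, drop the bottom 10%)
reduces the feature set to preset sizes; final models are trained on the
20-feature snapshot, in a **with-GO** and a **without-GO** variant with
automatic routing by annotation availability.

Performance is summarized by PPV, NPV, sensitivity, specificity, accuracy,
MCC, nMCC = (1+MCC)/2, rank-based AUC, coverage (fraction of non-UV calls),
and the overall performance measure

    OPM = (PPV + NPV)(Sensitivity + Specificity)(Accuracy + nMCC) / 8.

## Worked example

The package ships a synthetic-benchmark generator that plants the class
structure the features assume (pathogenic variants at conserved alignment
columns, with drastic hydropathy change, in proteins with disease-skewed
annotations), so the whole workflow runs with no downloads:

```sh
varitol simulate --out data --seed 1        # 300 proteins, 1800 variants
varitol pipeline --data data --out run --seed 1
```

`run/metrics.tsv` then holds the held-out report (360 test variants from
proteins never seen in training; values without rejection in brackets):

```
measure      all
accuracy     0.966 (0.964)
mcc          0.933 (0.928)
opm          0.903 (0.896)
coverage     0.992 (1.000)
```

i.e. the ensemble recovers the planted signal almost perfectly, abstains on
the ambiguous 0.8% of cases, and abstention strictly improves MCC.
`run/selected_features.json` shows the 10-feature RFE survivors led by
`go:lr` (GO log-odds), `cons:score` (conservation) and the hydropathy delta —
the same families that dominate real variant-tolerance predictors.

The metric arithmetic is exposed directly; for a confusion table
TP=1945, TN=1855, FP=143, FN=217:

```
$ varitol evaluate --counts 1945 1855 143 217
ppv         0.932
npv         0.895
sensitivity 0.9
specificity 0.928
accuracy    0.913
mcc         0.827
nmcc        0.914
opm         0.763
```

## Layout

| module | contents |
|---|---|
| `varitol.core` | protein/variant records, validation, protein-disjoint splitting, 1:1 balancing, grouped CV folds |
| `varitol.features` | AAindex parsing, propensity deltas, variation type, neighborhood, assembly |
| `varitol.conservation` | MSA column profiles, SIFT-style scores, precomputed-score override |
| `varitol.annotations` | OBO loading, ancestor closure, term-frequency tables, LR/FS |
| `varitol.model` | bootstrap LightGBM ensemble, Chebyshev reject, RFE, serialization |
| `varitol.evaluation` | the eight measures, coverage, rank AUC, cohort reports |
| `varitol.simulate` | synthetic benchmark generator (signal and null) |
| `varitol.pipeline`, `varitol.io`, `varitol.cli` | workflow binding, file formats, command line |

See `docs/methods.md` for modeling assumptions, parameter defaults, and
limitations.
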