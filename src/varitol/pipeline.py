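"""End-to-end workflow: features -> selection -> two-mode training -> evaluation.

Binds the feature extractors, annotation tables, reject-option ensemble
and evaluation into one leakage-free experiment:

1. balance classes 1:1 by undersampling;
2. protein-disjoint train/test split;
3. GO / site frequency tables built on training proteins only;
4. feature matrices for both sets;
5. recursive feature elimination (per mode) and ensemble training with
   and without the GO feature;
6. predictions routed per variant by GO availability, evaluated with and
   without rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from varitol import annotations as annot
from varitol import conservation as cons
from varitol.core import (
    DataSplit,
    ProteinRecord,
    VariantRecord,
    balance_classes,
    protein_disjoint_split,
    validate_variant,
)
from varitol.evaluation import evaluate_predictions
from varitol.features import AAindexScale, FeatureVector, assemble_features
from varitol.model import (
    DEFAULT_B,
    DEFAULT_CONFIDENCE,
    EnsembleModel,
    PredictionResult,
    predict_batch,
    rfe_select,
    train_ensemble,
)

#: Feature columns that require GO/site annotation; the without-GO model
#: is trained with these removed.
ANNOTATION_FEATURES = ("go:lr", "site:fs")


def build_tables(
    train_variants: Sequence[VariantRecord],
    go_annotations: Mapping[str, frozenset],
    site_annotations: Mapping[str, frozenset],
    dag: Optional[annot.OntologyDAG],
) -> Tuple[annot.TermFrequencyTable, annot.TermFrequencyTable]:
    """GO and site frequency tables from training variants only."""
    classes = annot.protein_class_labels(train_variants)
    go_table = annot.build_frequency_table(go_annotations, classes, dag)
    site_table = annot.build_frequency_table(site_annotations, classes, dag=None)
    return go_table, site_table


def extract_features(
    variant: VariantRecord,
    protein: ProteinRecord,
    scales: Sequence[AAindexScale],
    dag: Optional[annot.OntologyDAG] = None,
    go_table: Optional[annot.TermFrequencyTable] = None,
    site_table: Optional[annot.TermFrequencyTable] = None,
    precomputed_scores: Optional[Mapping] = None,
) -> FeatureVector:
    """Full feature vector for one validated variant."""
    validate_variant(variant, protein)
    homologs = protein.homolog_count
    score = None
    key = (variant.protein_id, variant.position, variant.alt_aa)
    if precomputed_scores and key in precomputed_scores:
        score = precomputed_scores[key]
    elif protein.msa is not None and len(protein.msa) > 1:
        score = cons.score_variant(protein.msa, variant.position, variant.alt_aa)
    lr = fs = None
    if go_table is not None and protein.go_terms:
        value, ok = annot.lr_score(protein.go_terms, go_table, dag)
        lr = value if ok else None
    if site_table is not None and protein.site_terms:
        value, ok = annot.fs_score(protein.site_terms, site_table)
        fs = value if ok else None
    return assemble_features(
        protein, variant, scales,
        homolog_count=homologs, conservation_score=score, lr=lr, fs=fs,
    )


def extract_matrix(
    variants: Sequence[VariantRecord],
    proteins: Mapping[str, ProteinRecord],
    scales: Sequence[AAindexScale],
    dag=None,
    go_table=None,
    site_table=None,
    precomputed_scores=None,
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """(values, availability mask, feature names) over a variant list."""
    vectors = [
        extract_features(
            v, proteins[v.protein_id], scales, dag, go_table, site_table,
            precomputed_scores,
        )
        for v in variants
    ]
    X = np.stack([fv.values for fv in vectors])
    M = np.stack([fv.mask for fv in vectors])
    return X, M, vectors[0].names


@dataclass
class ExperimentResult:
    """Everything a run produces: split, selections, models, reports."""

    split: DataSplit
    feature_names: List[str]
    selections: Dict[str, Dict[int, List[str]]]
    models: Dict[str, EnsembleModel]
    predictions: List[PredictionResult]
    test_labels: List[str]
    reports: Dict[str, Dict[str, object]]


def _train_mode(
    X: np.ndarray,
    y: np.ndarray,
    names: List[str],
    mode: str,
    rfe_targets: Optional[Sequence[int]],
    n_final: Optional[int],
    B: int,
    seed: int,
    params,
) -> Tuple[EnsembleModel, Dict[int, List[str]]]:
    if mode == "without_go":
        keep = [i for i, n in enumerate(names) if n not in ANNOTATION_FEATURES]
        X, names = X[:, keep], [names[i] for i in keep]
    selection: Dict[int, List[str]] = {}
    if rfe_targets:
        selection = rfe_select(X, y, names, rfe_targets, seed=seed, params=params)
    if n_final is not None and n_final in selection:
        chosen = selection[n_final]
        cols = [names.index(n) for n in chosen]
        X, names = X[:, cols], chosen
    model = train_ensemble(
        X, y, B=B, seed=seed, params=params, feature_names=list(names)
    )
    model.training_meta = dict(model.training_meta, mode=mode)
    return model, selection


def route_and_predict(
    models: Mapping[str, EnsembleModel],
    X: np.ndarray,
    M: np.ndarray,
    names: List[str],
    confidence: float = DEFAULT_CONFIDENCE,
) -> List[PredictionResult]:
    """Batch two-mode prediction: with-GO iff the LR feature is available."""
    lr_idx = names.index("go:lr")
    use_go = M[:, lr_idx] & ("with_go" in models)
    results: List[Optional[PredictionResult]] = [None] * X.shape[0]
    for mode, rows in (("with_go", np.where(use_go)[0]),
                       ("without_go", np.where(~use_go)[0])):
        if len(rows) == 0:
            continue
        model = models.get(mode) or models["with_go"]
        mode_used = mode if mode in models else "with_go"
        cols = [names.index(n) for n in model.feature_names]
        for row, res in zip(
            rows, predict_batch(model, X[np.ix_(rows, cols)], confidence, mode=mode_used)
        ):
            results[row] = res
    return list(results)


def run_experiment(
    benchmark,
    seed: int = 0,
    test_fraction: float = 0.2,
    B: int = DEFAULT_B,
    confidence: float = DEFAULT_CONFIDENCE,
    rfe_targets: Optional[Sequence[int]] = (100, 50, 20, 10),
    n_final_features: Optional[int] = 20,
    params: Optional[Mapping] = None,
    modes: Sequence[str] = ("with_go", "without_go"),
) -> ExperimentResult:
    """Run the full workflow on a benchmark bundle.

    ``rfe_targets=None`` skips selection and trains on all features;
    ``n_final_features`` picks the RFE snapshot the final ensembles are
    trained on (the 20-feature snapshot by default).
    """
    balanced = balance_classes(benchmark.variants, seed=seed)
    split = protein_disjoint_split(balanced, test_fraction, seed=seed)
    go_table, site_table = build_tables(
        split.train, benchmark.go_annotations, benchmark.site_annotations,
        benchmark.ontology,
    )
    kwargs = dict(
        proteins=benchmark.proteins, scales=benchmark.scales,
        dag=benchmark.ontology, go_table=go_table, site_table=site_table,
    )
    X_train, _, names = extract_matrix(split.train, **kwargs)
    X_test, M_test, _ = extract_matrix(split.test, **kwargs)
    y_train = np.array([v.label == "pathogenic" for v in split.train], dtype=int)

    models: Dict[str, EnsembleModel] = {}
    selections: Dict[str, Dict[int, List[str]]] = {}
    for mode in modes:
        model, selection = _train_mode(
            X_train, y_train, list(names), mode, rfe_targets,
            n_final_features, B, seed, params,
        )
        models[mode] = model
        selections[mode] = selection

    predictions = route_and_predict(models, X_test, M_test, names, confidence)
    test_labels = [v.label for v in split.test]
    reports = evaluate_predictions(predictions, test_labels)
    return ExperimentResult(
        split=split, feature_names=list(names), selections=selections,
        models=models, predictions=predictions, test_labels=test_labels,
        reports=reports,
    )
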