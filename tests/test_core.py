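"""Variant parsing, validation, and protein-disjoint partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varitol.core import (
    BENIGN,
    PATHOGENIC,
    ProteinRecord,
    VariantParseError,
    VariantRecord,
    balance_classes,
    cv_iter,
    make_cv_folds,
    parse_variant,
    protein_disjoint_split,
    validate_variant,
)
from conftest import make_variants


@pytest.mark.parametrize(
    "token, expected",
    [
        ("E41K", ("E", 41, "K")),
        ("p.E41K", ("E", 41, "K")),
        ("a5t", ("A", 5, "T")),
        ("W1234C", ("W", 1234, "C")),
    ],
)
def test_parse_variant_accepts_standard_tokens(token, expected):
    assert parse_variant(token) == expected


@pytest.mark.parametrize(
    "token",
    ["E41E", "X41K", "E41", "41K", "E-1K", "EK", "", "E41B", "p.p.E41K"],
)
def test_parse_variant_rejects_malformed_tokens(token):
    with pytest.raises(VariantParseError):
        parse_variant(token)


@settings(derandomize=True, max_examples=200)
@given(
    ref=st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
    alt=st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
    pos=st.integers(min_value=1, max_value=99999),
    prefix=st.booleans(),
)
def test_parse_variant_round_trip(ref, alt, pos, prefix):
    token = f"{'p.' if prefix else ''}{ref}{pos}{alt}"
    if ref == alt:
        with pytest.raises(VariantParseError):
            parse_variant(token)
    else:
        assert parse_variant(token) == (ref, pos, alt)


class TestValidateVariant:
    protein = ProteinRecord(id="p1", sequence="MKTE")

    def test_matching_reference_passes(self):
        v = VariantRecord("p1", 2, "K", "R")
        assert validate_variant(v, self.protein) is v

    def test_reference_mismatch_names_found_residue(self):
        with pytest.raises(VariantParseError, match="expected K, found T"):
            validate_variant(VariantRecord("p1", 3, "K", "R"), self.protein)

    def test_out_of_range_position(self):
        with pytest.raises(VariantParseError, match="out of range"):
            validate_variant(VariantRecord("p1", 9, "E", "A"), self.protein)


def test_protein_record_rejects_non_canonical_residues():
    with pytest.raises(ValueError, match="non-canonical"):
        ProteinRecord(id="p", sequence="MKXTE")
    with pytest.raises(ValueError, match="empty"):
        ProteinRecord(id="p", sequence="")


def test_protein_record_msa_row0_must_match_sequence():
    ProteinRecord(id="p", sequence="MKTE", msa=("MKTE",))  # single-row ok
    with pytest.raises(ValueError, match="row 0"):
        ProteinRecord(id="p", sequence="MKTE", msa=("MKTA", "MKTE"))
    with pytest.raises(ValueError, match="ragged"):
        ProteinRecord(id="p", sequence="MKTE", msa=("MKTE", "MK"))


class TestProteinDisjointSplit:
    def test_small_exact_split(self):
        variants = make_variants(10, 3, n_pathogenic=15)
        split = protein_disjoint_split(variants, 0.2, seed=1)
        test_proteins = {v.protein_id for v in split.test}
        assert len(test_proteins) == 2
        assert len(split.test) == 6
        split.check_disjoint()

    def test_determinism(self):
        variants = make_variants(10, 3, n_pathogenic=15)
        a = protein_disjoint_split(variants, 0.2, seed=1)
        b = protein_disjoint_split(variants, 0.2, seed=1)
        assert a.test == b.test and a.train == b.train

    def test_large_heterogeneous_fraction_and_disjointness(self):
        rng = np.random.default_rng(5)
        variants = []
        for i in range(1000):
            for j in range(int(rng.integers(1, 12))):
                variants.append(
                    VariantRecord(f"P{i:04d}", j + 1, "A", "V", PATHOGENIC)
                )
        split = protein_disjoint_split(variants, 0.3, seed=3)
        train_ids = {v.protein_id for v in split.train}
        test_ids = {v.protein_id for v in split.test}
        assert train_ids & test_ids == set()
        frac = len(split.test) / len(variants)
        assert abs(frac - 0.3) < 0.05

    def test_requires_two_proteins(self):
        variants = [VariantRecord("only", 1, "A", "V", PATHOGENIC)]
        with pytest.raises(ValueError):
            protein_disjoint_split(variants, 0.5, seed=0)


class TestBalanceClasses:
    def test_undersamples_majority_exactly(self):
        variants = make_variants(20, 7, n_pathogenic=100)  # 100 path + 40 benign
        balanced = balance_classes(variants, seed=0)
        n_path = sum(v.label == PATHOGENIC for v in balanced)
        n_ben = sum(v.label == BENIGN for v in balanced)
        assert n_path == n_ben == 40

    def test_identity_when_already_balanced(self):
        variants = make_variants(20, 4, n_pathogenic=40)
        assert balance_classes(variants, seed=0) == variants

    def test_determinism(self):
        variants = make_variants(20, 7, n_pathogenic=100)
        assert balance_classes(variants, seed=9) == balance_classes(variants, seed=9)

    def test_requires_both_classes(self):
        variants = make_variants(5, 2, n_pathogenic=10)
        with pytest.raises(ValueError):
            balance_classes(variants, seed=0)


class TestCvFolds:
    def test_even_protein_distribution(self):
        variants = make_variants(20, 3, n_pathogenic=30)
        split = make_cv_folds(variants, k=10, seed=0)
        per_fold = {}
        for pid, fold in split.fold_assignment.items():
            per_fold.setdefault(fold, set()).add(pid)
        assert len(per_fold) == 10
        assert all(len(p) == 2 for p in per_fold.values())

    def test_every_protein_in_exactly_one_fold(self):
        variants = make_variants(37, 2, n_pathogenic=37)
        split = make_cv_folds(variants, k=5, seed=2)
        assert set(split.fold_assignment) == {v.protein_id for v in variants}

    def test_skewed_counts_yield_nonempty_balanced_folds(self):
        rng = np.random.default_rng(0)
        variants = []
        for i in range(100):
            for j in range(int(rng.integers(1, 20))):
                variants.append(VariantRecord(f"P{i:03d}", j + 1, "A", "V", BENIGN))
        split = make_cv_folds(variants, k=10, seed=0)
        counts = np.zeros(10)
        for v in variants:
            counts[split.fold_assignment[v.protein_id]] += 1
        assert counts.min() > 0
        assert counts.max() / counts.min() < 1.5

    def test_cv_iter_is_protein_disjoint(self):
        variants = make_variants(12, 2, n_pathogenic=12)
        split = make_cv_folds(variants, k=4, seed=1)
        for _, train, test in cv_iter(variants, split.fold_assignment):
            assert {v.protein_id for v in train} & {v.protein_id for v in test} == set()
            assert len(train) + len(test) == len(variants)

    def test_errors(self):
        variants = make_variants(3, 2, n_pathogenic=3)
        with pytest.raises(ValueError):
            make_cv_folds(variants, k=1, seed=0)
        with pytest.raises(ValueError):
            make_cv_folds(variants, k=5, seed=0)
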