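"""Data model for proteins and variants, and leakage-free data partitioning.

Positions are 1-based everywhere, following protein variant nomenclature
(``E41K`` means residue 41, Glu replaced by Lys).  All splitting operations
are protein-disjoint: every variant of a protein falls on the same side of
a train/test split and into the same cross-validation fold, so that
protein-level features (GO log-odds, conservation profiles) cannot leak
between sets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

#: The 20 canonical one-letter amino acid codes, alphabetical.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

_AA_SET = frozenset(AMINO_ACIDS)

PATHOGENIC = "pathogenic"
BENIGN = "benign"
UNLABELED = "unlabeled"

_LABELS = (PATHOGENIC, BENIGN, UNLABELED)


class VariantParseError(ValueError):
    """A variant token or record could not be parsed or validated."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence plus the annotations used for feature extraction.

    Parameters
    ----------
    id : str
        Protein identifier (FASTA key).
    sequence : str
        Amino acid sequence over the 20 canonical one-letter codes.
    go_terms : frozenset of str
        Ontology term ids annotated to this protein (possibly empty).
    site_terms : frozenset of str
        Functional-site term keys (possibly empty).
    msa : tuple of str, optional
        Aligned homolog sequences; row 0 is this protein (with gaps).
    homolog_count : int, optional
        Number of database homologs; defaults to ``len(msa) - 1`` when an
        alignment is present.
    """

    id: str
    sequence: str
    go_terms: frozenset = frozenset()
    site_terms: frozenset = frozenset()
    msa: Optional[tuple] = None
    homolog_count: Optional[int] = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: non-canonical residue(s) "
                f"{sorted(bad)}; only the 20 canonical one-letter codes "
                "are accepted"
            )
        object.__setattr__(self, "go_terms", frozenset(self.go_terms))
        object.__setattr__(self, "site_terms", frozenset(self.site_terms))
        if self.msa is not None:
            msa = tuple(str(r) for r in self.msa)
            if not msa:
                raise ValueError(f"protein {self.id!r}: empty MSA")
            widths = {len(r) for r in msa}
            if len(widths) != 1:
                raise ValueError(
                    f"protein {self.id!r}: ragged MSA (row lengths {sorted(widths)})"
                )
            degapped = msa[0].replace("-", "").replace(".", "")
            if degapped != self.sequence:
                raise ValueError(
                    f"protein {self.id!r}: MSA row 0 degapped does not equal "
                    "the protein sequence"
                )
            object.__setattr__(self, "msa", msa)
        if self.homolog_count is None and self.msa is not None:
            object.__setattr__(self, "homolog_count", len(self.msa) - 1)
        if self.homolog_count is not None and self.homolog_count < 0:
            raise ValueError(f"protein {self.id!r}: negative homolog_count")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VariantRecord:
    """One amino acid substitution, 1-based, with an optional class label."""

    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str
    label: str = UNLABELED

    def __post_init__(self):
        for aa, which in ((self.ref_aa, "ref"), (self.alt_aa, "alt")):
            if aa not in _AA_SET:
                raise VariantParseError(
                    f"{self.protein_id} {self}: non-canonical {which} residue {aa!r}"
                )
        if self.ref_aa == self.alt_aa:
            raise VariantParseError(
                f"{self.protein_id}: ref and alt residues are identical "
                f"({self.ref_aa}{self.position}{self.alt_aa})"
            )
        if self.position < 1:
            raise VariantParseError(
                f"{self.protein_id}: position must be >= 1, got {self.position}"
            )
        if self.label not in _LABELS:
            raise ValueError(
                f"label must be one of {_LABELS}, got {self.label!r}"
            )

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass
class DataSplit:
    """A protein-disjoint train/test partition, optionally with CV folds."""

    train: list = field(default_factory=list)
    test: list = field(default_factory=list)
    fold_assignment: dict = field(default_factory=dict)

    def check_disjoint(self) -> None:
        train_p = {v.protein_id for v in self.train}
        test_p = {v.protein_id for v in self.test}
        overlap = train_p & test_p
        if overlap:
            raise AssertionError(
                f"train/test share proteins: {sorted(overlap)[:5]} ..."
            )


_VARIANT_RE = re.compile(r"^(?:p\.)?([A-Za-z])(\d+)([A-Za-z])$")


def parse_variant(token: str):
    """Parse a substitution token like ``E41K`` or ``p.E41K``.

    Returns
    -------
    (ref_aa, position, alt_aa) : tuple of (str, int, str)

    Raises
    ------
    VariantParseError
        If the token is malformed, uses a non-canonical letter, or has
        identical reference and alternate residues.
    """
    m = _VARIANT_RE.match(token.strip())
    if m is None:
        raise VariantParseError(
            f"malformed variant token {token!r}; expected <AA><position><AA> "
            "in one-letter codes, e.g. E41K"
        )
    ref, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    for aa in (ref, alt):
        if aa not in _AA_SET:
            raise VariantParseError(
                f"variant token {token!r}: non-canonical residue {aa!r}"
            )
    if ref == alt:
        raise VariantParseError(
            f"variant token {token!r}: reference and alternate residues are equal"
        )
    if pos < 1:
        raise VariantParseError(f"variant token {token!r}: position must be >= 1")
    return ref, pos, alt


def validate_variant(v: VariantRecord, p: ProteinRecord) -> VariantRecord:
    """Check a variant against its protein sequence (1-based position).

    Raises
    ------
    VariantParseError
        If the position is out of range or the sequence residue at the
        position differs from the stated reference residue.
    """
    if p.id != v.protein_id:
        raise ValueError(
            f"variant references protein {v.protein_id!r} but got {p.id!r}"
        )
    if v.position > p.length:
        raise VariantParseError(
            f"{p.id} {v}: position {v.position} out of range "
            f"(sequence length {p.length})"
        )
    found = p.sequence[v.position - 1]
    if found != v.ref_aa:
        raise VariantParseError(
            f"{p.id} {v}: reference mismatch at position {v.position}: "
            f"expected {v.ref_aa}, found {found}"
        )
    return v


def _group_by_protein(variants: Sequence[VariantRecord]) -> dict:
    groups: dict = {}
    for v in variants:
        groups.setdefault(v.protein_id, []).append(v)
    return groups


def protein_disjoint_split(
    variants: Sequence[VariantRecord],
    test_fraction: float,
    seed: int,
) -> DataSplit:
    """Partition variants into train/test with whole proteins on one side.

    Proteins are shuffled with the given seed and assigned greedily to the
    test set until the realized test variant fraction reaches
    ``test_fraction``.  The protein-id sets of train and test are disjoint
    by construction.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    groups = _group_by_protein(variants)
    if len(groups) < 2:
        raise ValueError("need at least 2 proteins to split")
    rng = np.random.default_rng(seed)
    order = sorted(groups)
    rng.shuffle(order)
    n_total = len(variants)
    target = test_fraction * n_total
    test_ids, n_test = set(), 0
    for pid in order:
        if n_test >= target:
            break
        test_ids.add(pid)
        n_test += len(groups[pid])
    # never put every protein in test
    if len(test_ids) == len(groups):
        test_ids.discard(order[-1])
    split = DataSplit(
        train=[v for v in variants if v.protein_id not in test_ids],
        test=[v for v in variants if v.protein_id in test_ids],
    )
    split.check_disjoint()
    return split


def balance_classes(
    variants: Sequence[VariantRecord], seed: int
) -> list:
    """Balance pathogenic vs benign counts to exact 1:1 by undersampling.

    The majority class is randomly undersampled (seeded, without
    replacement); the minority class is untouched.  Undersampling rather
    than oversampling avoids duplicated variants leaking across bootstrap
    resamples downstream.
    """
    path = [v for v in variants if v.label == PATHOGENIC]
    ben = [v for v in variants if v.label == BENIGN]
    if not path or not ben:
        raise ValueError(
            "both classes must be present to balance "
            f"(pathogenic={len(path)}, benign={len(ben)})"
        )
    rng = np.random.default_rng(seed)
    if len(path) > len(ben):
        keep = rng.choice(len(path), size=len(ben), replace=False)
        path = [path[i] for i in sorted(keep)]
    elif len(ben) > len(path):
        keep = rng.choice(len(ben), size=len(path), replace=False)
        ben = [ben[i] for i in sorted(keep)]
    kept = set(map(id, path)) | set(map(id, ben))
    return [v for v in variants if id(v) in kept]


def make_cv_folds(
    variants: Sequence[VariantRecord], k: int = 10, seed: int = 0
) -> DataSplit:
    """Assign whole proteins to ``k`` cross-validation folds.

    After a seeded shuffle, proteins are placed in descending order of
    variant count onto the currently lightest fold (greedy bin packing),
    which keeps per-fold variant counts as even as the protein grouping
    permits.  The returned ``DataSplit`` carries only ``fold_assignment``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    groups = _group_by_protein(variants)
    if len(groups) < k:
        raise ValueError(f"need at least {k} proteins for {k}-fold CV, "
                         f"got {len(groups)}")
    rng = np.random.default_rng(seed)
    order = sorted(groups)
    rng.shuffle(order)
    # stable sort: ties keep shuffled order
    order.sort(key=lambda pid: -len(groups[pid]))
    loads = np.zeros(k, dtype=int)
    assignment = {}
    for pid in order:
        fold = int(np.argmin(loads))
        assignment[pid] = fold
        loads[fold] += len(groups[pid])
    return DataSplit(train=list(variants), test=[], fold_assignment=assignment)


def cv_iter(variants: Sequence[VariantRecord], fold_assignment: Mapping[str, int]):
    """Yield (fold_index, train_variants, test_variants) per CV fold."""
    k = max(fold_assignment.values()) + 1
    for fold in range(k):
        train = [v for v in variants if fold_assignment[v.protein_id] != fold]
        test = [v for v in variants if fold_assignment[v.protein_id] == fold]
        yield fold, train, test
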