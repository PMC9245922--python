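"""Per-variant feature extraction.

Four feature families computed directly from the sequence and the
substitution, plus slots for the conservation and annotation features
supplied by the :mod:`varitol.conservation` and :mod:`varitol.annotations`
modules:

* amino acid propensity deltas — one per loaded AAindex scale,
  ``scale[ref] - scale[alt]``;
* variation-type indicators — a 400-element one-hot over ordered
  (ref, alt) residue pairs plus a 36-element one-hot over ordered pairs of
  six physicochemical classes;
* neighborhood composition — 20 residue counts and 5 group frequencies in
  a window of 23 positions (11 each side of the variant, center included,
  truncated at sequence ends);
* protein features — sequence length, first-residue flag, and the variant
  position.

Feature ordering is fixed (scales in file order, then the families in the
order above) so that saved models remain valid across sessions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from varitol.core import AMINO_ACIDS, ProteinRecord, VariantRecord

# ---------------------------------------------------------------------------
# AAindex propensity scales

#: Residue order of the AAindex1 `I` record (two rows of ten).
_AAINDEX_ORDER = "ARNDCQEGHILKMFPSTWVY"


@dataclass(frozen=True)
class AAindexScale:
    """One complete amino acid propensity scale (20 finite values)."""

    accession: str
    description: str
    values: Dict[str, float]

    def __post_init__(self):
        if set(self.values) != set(AMINO_ACIDS):
            raise ValueError(
                f"scale {self.accession}: expected exactly 20 residues, "
                f"got {len(self.values)}"
            )
        if not all(np.isfinite(list(self.values.values()))):
            raise ValueError(f"scale {self.accession}: non-finite value")


def load_aaindex(path) -> List[AAindexScale]:
    """Parse an AAindex1 flat file, keeping only complete scales.

    Records are delimited by ``//``; the ``I`` line is followed by two
    rows of ten values in the standard ``A R N D C Q E G H I / L K M F P
    S T W V Y`` order.  Scales containing ``NA`` (or any non-finite
    entry) are silently dropped; file order is preserved.
    """
    scales: List[AAindexScale] = []
    accession, description = None, ""
    value_tokens: List[str] = []
    in_values = False
    with open(path) as fh:
        any_record = False
        for line in fh:
            if line.startswith("//"):
                any_record = True
                if accession is not None and value_tokens:
                    scale = _finish_scale(accession, description, value_tokens)
                    if scale is not None:
                        scales.append(scale)
                accession, description = None, ""
                value_tokens, in_values = [], False
            elif line.startswith("H "):
                accession = line[2:].strip()
            elif line.startswith("D "):
                description = line[2:].strip()
            elif line.startswith("I "):
                in_values = True
            elif in_values and line.startswith(" "):
                value_tokens.extend(line.split())
            else:
                in_values = False
    if not any_record:
        raise ValueError(f"{path}: no AAindex records found (missing '//')")
    return scales


def _finish_scale(accession, description, tokens) -> Optional[AAindexScale]:
    if len(tokens) != 20:
        raise ValueError(
            f"scale {accession}: expected 20 values, got {len(tokens)}"
        )
    values = {}
    for aa, tok in zip(_AAINDEX_ORDER, tokens):
        try:
            x = float(tok)
        except ValueError:
            return None  # "NA" or similar: incomplete scale
        if not np.isfinite(x):
            return None
        values[aa] = x
    return AAindexScale(accession, description, values)


def aaindex_delta(scale: AAindexScale, ref_aa: str, alt_aa: str) -> float:
    """Difference ``scale[ref] - scale[alt]`` for one substitution."""
    try:
        return scale.values[ref_aa] - scale.values[alt_aa]
    except KeyError as exc:
        raise KeyError(
            f"residue {exc.args[0]!r} absent from scale {scale.accession}"
        ) from None


# ---------------------------------------------------------------------------
# Variation-type indicators

#: Six physicochemical residue classes.
AA_CLASSES: Dict[str, str] = {}
_CLASS_DEF = [
    ("hydrophobic", "VILFMWYC"),
    ("negative", "DE"),
    ("positive", "RKH"),
    ("conformational", "GP"),
    ("polar", "NQS"),
    ("other", "AT"),
]
for _name, _members in _CLASS_DEF:
    for _aa in _members:
        AA_CLASSES[_aa] = _name

CLASS_NAMES = [name for name, _ in _CLASS_DEF]


def aa_class(aa: str) -> str:
    """Map a residue to one of the six physicochemical classes."""
    try:
        return AA_CLASSES[aa]
    except KeyError:
        raise ValueError(f"non-canonical residue {aa!r}") from None


_PAIR_INDEX = {
    (r, a): i for i, (r, a) in enumerate(product(AMINO_ACIDS, AMINO_ACIDS))
}
_CLASS_PAIR_INDEX = {
    (r, a): i for i, (r, a) in enumerate(product(CLASS_NAMES, CLASS_NAMES))
}


def variation_type_features(ref_aa: str, alt_aa: str) -> np.ndarray:
    """436-element indicator block: 20x20 residue-pair + 6x6 class-pair.

    Exactly one of the 400 residue-pair positions and one of the 36
    class-pair positions is hot.  Residue pairs are ordered by the
    alphabetical 20-letter code; class pairs by hydrophobic, negative,
    positive, conformational, polar, other.
    """
    if ref_aa == alt_aa:
        raise ValueError("ref and alt residues must differ")
    out = np.zeros(436)
    try:
        out[_PAIR_INDEX[(ref_aa, alt_aa)]] = 1.0
    except KeyError:
        raise ValueError(
            f"non-canonical residue in pair ({ref_aa!r}, {alt_aa!r})"
        ) from None
    ci = _CLASS_PAIR_INDEX[(aa_class(ref_aa), aa_class(alt_aa))]
    out[400 + ci] = 1.0
    return out


# ---------------------------------------------------------------------------
# Neighborhood composition

#: Residue groups for the five neighborhood frequencies.  Charged is the
#: union of positive and negative, so the five frequencies are not a
#: partition and do not sum to one.
NEIGHBOR_GROUPS: Dict[str, frozenset] = {
    "nonpolar": frozenset("AVLIPFMWG"),
    "polar": frozenset("STCYNQ"),
    "charged": frozenset("DEKRH"),
    "positive": frozenset("KRH"),
    "negative": frozenset("DE"),
}

NEIGHBOR_GROUP_ORDER = ["nonpolar", "polar", "charged", "positive", "negative"]

#: Half-width of the neighborhood window (11 before + center + 11 after = 23).
WINDOW_HALF = 11


def neighborhood_features(sequence: str, position: int) -> np.ndarray:
    """20 residue counts + 5 group frequencies in the 23-residue window.

    The window spans 11 positions either side of the variant site,
    includes the (reference) center residue, and is truncated at sequence
    ends; group frequencies divide by the realized window size.
    """
    if not 1 <= position <= len(sequence):
        raise ValueError(
            f"position {position} out of range for sequence of length "
            f"{len(sequence)}"
        )
    lo = max(0, position - 1 - WINDOW_HALF)
    hi = min(len(sequence), position + WINDOW_HALF)
    window = sequence[lo:hi]
    counts = np.array([window.count(aa) for aa in AMINO_ACIDS], dtype=float)
    size = len(window)
    freqs = np.array(
        [
            sum(1 for aa in window if aa in NEIGHBOR_GROUPS[g]) / size
            for g in NEIGHBOR_GROUP_ORDER
        ]
    )
    return np.concatenate([counts, freqs])


# ---------------------------------------------------------------------------
# Protein features


def protein_features(p: ProteinRecord, v: VariantRecord) -> Tuple[int, int, int]:
    """(sequence length, first-residue flag, 1-based variant position)."""
    return p.length, int(v.position == 1), v.position


# ---------------------------------------------------------------------------
# Assembly


@dataclass
class FeatureVector:
    """Named feature values with per-feature availability flags.

    ``mask[i]`` is False when feature ``names[i]`` could not be computed
    for this variant (e.g. the GO log-odds of an unannotated protein);
    the value is then fixed at 0.
    """

    names: List[str]
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if len(self.names) != len(set(self.names)):
            raise ValueError("duplicate feature names")
        if not (len(self.names) == len(self.values) == len(self.mask)):
            raise ValueError("names/values/mask length mismatch")

    def __len__(self) -> int:
        return len(self.names)


def feature_names(scales: Sequence[AAindexScale]) -> List[str]:
    """The fixed, versioned feature ordering for a given scale list."""
    names = [f"aa:{s.accession}" for s in scales]
    names += [f"vt:{r}{a}" for r, a in product(AMINO_ACIDS, AMINO_ACIDS)]
    names += [f"vt6:{r}>{a}" for r, a in product(CLASS_NAMES, CLASS_NAMES)]
    names += [f"nb:count_{aa}" for aa in AMINO_ACIDS]
    names += [f"nb:freq_{g}" for g in NEIGHBOR_GROUP_ORDER]
    names += ["cons:homologs", "cons:score"]
    names += ["prot:length", "prot:first_residue", "prot:position"]
    names += ["go:lr", "site:fs"]
    if len(names) != len(set(names)):
        raise ValueError("feature name collision")
    return names


def assemble_features(
    p: ProteinRecord,
    v: VariantRecord,
    scales: Sequence[AAindexScale],
    homolog_count: Optional[float] = None,
    conservation_score: Optional[float] = None,
    lr: Optional[float] = None,
    fs: Optional[float] = None,
) -> FeatureVector:
    """Concatenate all feature families for one validated variant.

    ``homolog_count``, ``conservation_score``, ``lr`` and ``fs`` may be
    None when the corresponding provider has no data for this protein;
    the feature is then zero with ``mask`` False.
    """
    names = feature_names(scales)
    deltas = np.array([aaindex_delta(s, v.ref_aa, v.alt_aa) for s in scales])
    vt = variation_type_features(v.ref_aa, v.alt_aa)
    nb = neighborhood_features(p.sequence, v.position)
    length, first, pos = protein_features(p, v)
    if homolog_count is None:
        homolog_count = p.homolog_count

    optional = [homolog_count, conservation_score]
    tail = [length, first, pos]
    annot = [lr, fs]
    values = np.concatenate(
        [
            deltas,
            vt,
            nb,
            [0.0 if x is None else float(x) for x in optional],
            tail,
            [0.0 if x is None else float(x) for x in annot],
        ]
    )
    mask = np.ones(len(values), dtype=bool)
    base = len(deltas) + len(vt) + len(nb)
    mask[base] = homolog_count is not None
    mask[base + 1] = conservation_score is not None
    mask[base + 5] = lr is not None
    mask[base + 6] = fs is not None
    return FeatureVector(names=names, values=values, mask=mask)
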