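"""Evolutionary conservation features from a multiple sequence alignment.

Two features per variant: the number of homologs (MSA rows minus the
query) and a normalized substitution-tolerance score in the style of
SIFT.  The score at a query position is the pseudocount-smoothed
probability of the alternate residue in the alignment column, divided by
the probability of the most frequent residue; a value near 1 means the
substitution is common among homologs (tolerated), a value near 0 means
the column is conserved against it.

Precomputed scores from an external tool (e.g. SIFT 4G) can be loaded
from a TSV and override the MSA-derived values.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

from varitol.core import AMINO_ACIDS

#: Additive smoothing applied per residue when forming column probabilities.
DEFAULT_PSEUDOCOUNT = 0.1

_GAPS = {"-", "."}


@dataclass(frozen=True)
class ColumnProfile:
    """Residue probabilities of one alignment column (query coordinates)."""

    position: int
    probabilities: Dict[str, float]
    depth: int

    def __post_init__(self):
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")
        if self.depth < 1:
            raise ValueError("column depth must be >= 1")


def count_homologs(msa: Sequence[str]) -> int:
    """Number of alignment rows excluding the query (row 0)."""
    if not msa:
        raise ValueError("empty alignment")
    widths = {len(r) for r in msa}
    if len(widths) != 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(widths)}")
    return len(msa) - 1


def column_profile(
    msa: Sequence[str],
    query_position: int,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ColumnProfile:
    """Smoothed residue probabilities at an ungapped query position.

    The 1-based ``query_position`` indexes the query's own (degapped)
    sequence and is mapped to the corresponding alignment column.  Gap
    characters are excluded from counts and depth.  Probabilities are
    ``(count + pseudocount) / (depth + 20 * pseudocount)``.
    """
    count_homologs(msa)  # validates shape
    query = msa[0]
    ungapped = 0
    column = None
    for col, ch in enumerate(query):
        if ch not in _GAPS:
            ungapped += 1
            if ungapped == query_position:
                column = col
                break
    if column is None:
        raise ValueError(
            f"query position {query_position} out of range "
            f"(query has {ungapped} residues)"
        )
    residues = [row[column] for row in msa if row[column] not in _GAPS]
    depth = len(residues)
    denom = depth + 20 * pseudocount
    probs = {
        aa: (residues.count(aa) + pseudocount) / denom for aa in AMINO_ACIDS
    }
    return ColumnProfile(position=query_position, probabilities=probs, depth=depth)


def conservation_score(profile: ColumnProfile, alt_aa: str) -> float:
    """p(alt) / max p(.), in [0, 1]; 1 means alt is (tied for) consensus."""
    p_alt = profile.probabilities[alt_aa]
    p_max = max(profile.probabilities.values())
    return p_alt / p_max


def score_variant(
    msa: Sequence[str],
    position: int,
    alt_aa: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Convenience: column profile + conservation score in one call."""
    return conservation_score(column_profile(msa, position, pseudocount), alt_aa)


def load_precomputed_scores(path) -> Dict[Tuple[str, int, str], float]:
    """Load externally computed tolerance scores from a TSV.

    Columns: ``protein_id  position  alt_aa  score`` with header.  Scores
    must lie in [0, 1]; duplicate (protein, position, alt) keys are an
    error.  Entries override MSA-derived scores during feature extraction.
    """
    scores: Dict[Tuple[str, int, str], float] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            key = (row["protein_id"], int(row["position"]), row["alt_aa"])
            score = float(row["score"])
            if not 0.0 <= score <= 1.0:
                raise ValueError(
                    f"score {score} for {key} outside [0, 1]"
                )
            if key in scores:
                raise ValueError(f"duplicate precomputed-score key {key}")
            scores[key] = score
    return scores
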