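"""Readers and writers for the pipeline's on-disk formats.

Sequences are multi-FASTA keyed by protein id; alignments are aligned
FASTA, one file per protein named ``<protein_id>.fasta`` with the query
first; variants and annotations are headered TSVs; the ontology is OBO.
"""

from __future__ import annotations

import csv
import os
from typing import Dict, List, Optional, Tuple

from Bio import SeqIO

from varitol.core import UNLABELED, VariantRecord


def read_fasta(path) -> Dict[str, str]:
    """Protein sequences keyed by FASTA id."""
    sequences = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA id {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise ValueError(f"{path}: no FASTA records")
    return sequences


def read_msa(path) -> Tuple[str, ...]:
    """One aligned FASTA; the first record is the query."""
    rows = [str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise ValueError(f"{path}: empty alignment")
    return tuple(rows)


def read_msa_dir(path) -> Dict[str, Tuple[str, ...]]:
    """All ``<protein_id>.fasta`` alignments under a directory."""
    alignments = {}
    for fname in sorted(os.listdir(path)):
        if fname.endswith((".fasta", ".fa", ".afa")):
            pid = fname.rsplit(".", 1)[0]
            alignments[pid] = read_msa(os.path.join(path, fname))
    return alignments


_LABEL_ALIASES = {
    "pathogenic": "pathogenic",
    "benign": "benign",
    ".": UNLABELED,
    "": UNLABELED,
    "unlabeled": UNLABELED,
}


def read_variants_tsv(path) -> Tuple[List[VariantRecord], List[Tuple[dict, str]]]:
    """Parse a variant table; malformed rows go to a rejects list.

    Columns: ``protein_id  position  ref_aa  alt_aa  label`` with header;
    label is ``pathogenic``, ``benign`` or ``.``.  Returns
    (variants, rejects) where each reject is (raw_row, reason) — rows are
    reported, never silently dropped.
    """
    variants: List[VariantRecord] = []
    rejects: List[Tuple[dict, str]] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            try:
                variants.append(
                    VariantRecord(
                        protein_id=row["protein_id"],
                        position=int(row["position"]),
                        ref_aa=row["ref_aa"].upper(),
                        alt_aa=row["alt_aa"].upper(),
                        label=_LABEL_ALIASES[row["label"].strip().lower()],
                    )
                )
            except (KeyError, ValueError) as exc:
                rejects.append((dict(row), str(exc)))
    return variants, rejects


def read_annotations_tsv(path) -> Dict[str, frozenset]:
    """``protein_id  term_id`` TSV -> protein_id -> set of terms."""
    table: Dict[str, set] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            table.setdefault(row["protein_id"], set()).add(row["term_id"])
    return {pid: frozenset(terms) for pid, terms in table.items()}


def write_predictions_tsv(path, rows) -> None:
    """Prediction table: protein_id, variant, mu, sigma, decision, mode."""
    with open(path, "w") as fh:
        fh.write("protein_id\tvariant\tmu\tsigma\tdecision\tmode\n")
        for pid, variant, result in rows:
            fh.write(
                f"{pid}\t{variant}\t{result.mu:.6f}\t{result.sigma:.6f}"
                f"\t{result.decision}\t{result.mode or '.'}\n"
            )


def write_rejects_tsv(path, rejects) -> None:
    with open(path, "w") as fh:
        fh.write("row\treason\n")
        for row, reason in rejects:
            fh.write(f"{row}\t{reason}\n")


def write_metric_report_tsv(path, reports) -> None:
    """Metric x cohort table mirroring the bracketed with/without layout."""
    metrics = ["ppv", "npv", "sensitivity", "specificity", "accuracy",
               "mcc", "nmcc", "opm", "auc", "coverage"]
    cohorts = sorted(reports, key=lambda c: (c != "all", c))
    with open(path, "w") as fh:
        fh.write("measure\t" + "\t".join(cohorts) + "\n")
        for m in metrics:
            cells = []
            for c in cohorts:
                with_rej = getattr(reports[c]["with_rejection"], m)
                without = getattr(reports[c]["without_rejection"], m)
                fmt = lambda v: "NA" if v is None else f"{v:.3f}"
                cells.append(f"{fmt(with_rej)} ({fmt(without)})")
            fh.write(m + "\t" + "\t".join(cells) + "\n")
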