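"""GO and functional-site log-odds features.

A protein's GO annotation is first closed over the ontology DAG (every
transitive ancestor via is_a / part_of is added, each term counted once
per protein).  From the training proteins, a per-term frequency table
counts how many distinct pathogenic-class and neutral-class proteins
carry each term.  The LR feature of a protein is then

    LR = sum over its closed terms t of ln((f_P(t) + 1) / (f_N(t) + 1))

where f_P and f_N are the raw per-class protein counts; the +1 smoothing
avoids undefined ratios.  FS is the same statistic over functional-site
terms (no ontology closure).  An unannotated protein scores 0 and the
feature is flagged unavailable so prediction can fall back to the
model trained without annotation features.

Frequency tables must be built from training folds only; building them
on test proteins leaks label information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Set, Tuple

import networkx as nx

from varitol.core import BENIGN, PATHOGENIC


@dataclass(frozen=True)
class OntologyDAG:
    """Parent links (is_a, part_of) of an ontology; validated acyclic."""

    parents: Mapping[str, frozenset]

    def __post_init__(self):
        parents = {t: frozenset(ps) for t, ps in self.parents.items()}
        unknown = {
            p for ps in parents.values() for p in ps if p not in parents
        }
        if unknown:
            raise ValueError(
                f"parent terms not defined in the ontology: {sorted(unknown)[:5]}"
            )
        g = nx.DiGraph(
            (t, p) for t, ps in parents.items() for p in ps
        )
        g.add_nodes_from(parents)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology contains a cycle")
        object.__setattr__(self, "parents", parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents


def load_obo(path) -> OntologyDAG:
    """Read an OBO file, keeping is_a and part_of edges."""
    import obonet

    graph = obonet.read_obo(path)
    parents: Dict[str, Set[str]] = {t: set() for t in graph.nodes}
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a" or key == "part_of":
            parents[child].add(parent)
    return OntologyDAG(parents=parents)


def ancestor_closure(terms: Iterable[str], dag: OntologyDAG) -> frozenset:
    """The input terms plus all their transitive ancestors, deduplicated."""
    closed: Set[str] = set()
    stack = list(terms)
    for t in stack:
        if t not in dag:
            raise KeyError(f"unknown ontology term {t!r}")
    while stack:
        t = stack.pop()
        if t in closed:
            continue
        closed.add(t)
        stack.extend(dag.parents[t])
    return frozenset(closed)


@dataclass
class TermFrequencyTable:
    """Per-term counts of distinct pathogenic / neutral training proteins."""

    counts: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    n_proteins: Tuple[int, int] = (0, 0)

    def pathogenic(self, term: str) -> int:
        return self.counts.get(term, (0, 0))[0]

    def neutral(self, term: str) -> int:
        return self.counts.get(term, (0, 0))[1]


def protein_class_labels(
    variants, *, pathogenic_label: str = PATHOGENIC, benign_label: str = BENIGN
) -> Dict[str, Set[str]]:
    """Map protein_id -> set of class labels its training variants carry.

    A protein with at least one pathogenic training variant counts as
    pathogenic; one with at least one benign variant counts as neutral; a
    protein carrying both contributes to both class tallies.
    """
    classes: Dict[str, Set[str]] = {}
    for v in variants:
        if v.label == pathogenic_label:
            classes.setdefault(v.protein_id, set()).add(PATHOGENIC)
        elif v.label == benign_label:
            classes.setdefault(v.protein_id, set()).add(BENIGN)
    return classes


def build_frequency_table(
    protein_terms: Mapping[str, Iterable[str]],
    protein_classes: Mapping[str, Set[str]],
    dag: Optional[OntologyDAG] = None,
) -> TermFrequencyTable:
    """Count, per term, the distinct training proteins of each class.

    ``protein_terms`` maps protein_id -> raw term annotation; terms are
    closed over ``dag`` when given (GO) and deduplicated per protein, so
    each protein contributes each term at most once.  Proteins absent
    from ``protein_classes`` (no labeled training variant) are ignored.
    """
    counts: Dict[str, list] = {}
    n_path = n_neut = 0
    for pid, classes in protein_classes.items():
        terms = protein_terms.get(pid, ())
        closed = ancestor_closure(terms, dag) if dag is not None else set(terms)
        is_path = PATHOGENIC in classes
        is_neut = BENIGN in classes
        n_path += is_path
        n_neut += is_neut
        for t in closed:
            c = counts.setdefault(t, [0, 0])
            c[0] += is_path
            c[1] += is_neut
    return TermFrequencyTable(
        counts={t: (c[0], c[1]) for t, c in counts.items()},
        n_proteins=(n_path, n_neut),
    )


def log_odds_sum(
    terms: Iterable[str], table: TermFrequencyTable
) -> Tuple[float, bool]:
    """Sum of ln((f_P + 1) / (f_N + 1)) over terms; (0.0, False) if empty."""
    terms = set(terms)
    if not terms:
        return 0.0, False
    total = sum(
        math.log((table.pathogenic(t) + 1) / (table.neutral(t) + 1))
        for t in terms
    )
    return total, True


def lr_score(
    protein_terms: Iterable[str],
    table: TermFrequencyTable,
    dag: Optional[OntologyDAG] = None,
) -> Tuple[float, bool]:
    """GO log-odds feature of one protein; closure applied when dag given.

    Returns (value, available).  An unannotated protein yields
    (0.0, False): the value is a placeholder and prediction should route
    to the model trained without GO features.
    """
    terms = set(protein_terms)
    if not terms:
        return 0.0, False
    if dag is not None:
        terms = ancestor_closure(terms, dag)
    return log_odds_sum(terms, table)


def fs_score(
    protein_site_terms: Iterable[str], site_table: TermFrequencyTable
) -> Tuple[float, bool]:
    """Functional-site log-odds feature; flat term set, no closure."""
    return log_odds_sum(set(protein_site_terms), site_table)
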