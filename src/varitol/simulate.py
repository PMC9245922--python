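"""Self-contained synthetic benchmarks with planted class signal.

The generator emulates the statistical structure the feature families
assume of real data: pathogenic substitutions are enriched at
evolutionarily conserved alignment columns, biased toward drastic
physicochemical (hydropathy) change, and occur in proteins whose GO and
functional-site annotations are skewed toward a "disease" term pool.
Benign substitutions mirror each bias.  Every effect parameter is a
mixing weight in [0, 1]: with probability equal to the effect the
class-informative behavior applies, otherwise the choice is class-blind,
so zeroing all effects yields a null benchmark whose labels are
independent of every feature.

All randomness flows from one master seed through named
``numpy.random.SeedSequence`` child streams (sequences, alignments,
variants, annotations, scales), so output is bit-reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np

from varitol.core import (
    AMINO_ACIDS,
    BENIGN,
    PATHOGENIC,
    ProteinRecord,
    VariantRecord,
)
from varitol.annotations import OntologyDAG
from varitol.features import AAindexScale

#: Kyte-Doolittle hydropathy index; the physicochemical axis along which
#: the delta effect biases pathogenic substitutions.
HYDROPATHY: Dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic benchmark; defaults are the strong-signal
    study conditions (300 proteins, effects 0.9 / 0.8 / 0.8)."""

    n_proteins: int = 300
    mean_length: int = 250
    n_variants_per_protein: int = 6
    fraction_pathogenic: float = 0.5
    conservation_effect: float = 0.9
    delta_effect: float = 0.8
    n_go_terms: int = 60
    go_skew: float = 0.8
    msa_depth: int = 25
    n_scales: int = 40
    n_site_terms: int = 12
    fraction_unannotated: float = 0.1
    conserved_fraction: float = 0.35
    seed: int = 0

    def __post_init__(self):
        for name in ("fraction_pathogenic", "conservation_effect",
                     "delta_effect", "go_skew", "fraction_unannotated",
                     "conserved_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_proteins", "mean_length", "n_variants_per_protein",
                     "n_go_terms", "msa_depth", "n_scales", "n_site_terms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SyntheticBenchmark:
    """An internally consistent bundle of everything the pipeline reads."""

    proteins: Dict[str, ProteinRecord]
    variants: List[VariantRecord]
    ontology: OntologyDAG
    go_annotations: Dict[str, frozenset]
    site_annotations: Dict[str, frozenset]
    scales: List[AAindexScale]
    conserved_columns: Dict[str, frozenset] = field(default_factory=dict)
    config: SimulationConfig = field(default_factory=SimulationConfig)


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _make_ontology(n_leaves: int) -> Tuple[OntologyDAG, List[str], List[str]]:
    """Three-level balanced DAG: root, mid terms, leaves (two pools)."""
    root = "GO:0000001"
    n_mid = max(2, n_leaves // 10)
    mids = [f"GO:{1 + i + 1:07d}" for i in range(n_mid)]
    leaves = [f"GO:{1 + n_mid + i + 1:07d}" for i in range(n_leaves)]
    parents: Dict[str, set] = {root: set()}
    for m in mids:
        parents[m] = {root}
    for i, leaf in enumerate(leaves):
        parents[leaf] = {mids[i % n_mid]}
        if i % 3 == 0:  # a part_of-style second parent: exercises DAG closure
            parents[leaf].add(mids[(i + 1) % n_mid])
    dag = OntologyDAG(parents=parents)
    half = n_leaves // 2
    return dag, leaves[:half], leaves[half:]


def _make_scales(rng: np.random.Generator, n_scales: int) -> List[AAindexScale]:
    """Hydropathy first, then random propensity scales."""
    scales = [AAindexScale("HYDKD0101", "Hydropathy index", dict(HYDROPATHY))]
    for i in range(n_scales - 1):
        values = {aa: round(float(x), 3)
                  for aa, x in zip(AMINO_ACIDS, rng.normal(0, 1, 20))}
        scales.append(AAindexScale(f"SYN{i:04d}01", f"Synthetic scale {i}", values))
    return scales


def _make_msa(
    rng: np.random.Generator, sequence: str, depth: int, conserved: frozenset
) -> Tuple[str, ...]:
    """Query + homolog rows; conserved columns keep the query residue."""
    length = len(sequence)
    rows = [sequence]
    for _ in range(depth):
        chars = []
        for j in range(length):
            if j + 1 in conserved:
                keep = rng.random() < 0.95
            else:
                keep = rng.random() < 0.2
            if keep:
                chars.append(sequence[j])
            elif rng.random() < 0.02:
                chars.append("-")
            else:
                chars.append(AMINO_ACIDS[rng.integers(20)])
        rows.append("".join(chars))
    return tuple(rows)


def _pick_alt(
    rng: np.random.Generator, ref: str, label: str, effect: float
) -> str:
    """Alternate residue; with prob ``effect`` biased along hydropathy."""
    others = [aa for aa in AMINO_ACIDS if aa != ref]
    if rng.random() >= effect:
        return others[rng.integers(len(others))]
    others.sort(key=lambda aa: abs(HYDROPATHY[aa] - HYDROPATHY[ref]))
    pool = others[-4:] if label == PATHOGENIC else others[:4]
    return pool[rng.integers(len(pool))]


def _pick_position(
    rng: np.random.Generator,
    label: str,
    effect: float,
    conserved: list,
    nonconserved: list,
    used: set,
) -> int:
    """Variant position; with prob ``effect`` class-informative w.r.t.
    conservation, else uniform over the whole sequence."""
    informative = rng.random() < effect
    if informative:
        pool = conserved if label == PATHOGENIC else nonconserved
    else:
        pool = conserved + nonconserved
    free = [p for p in pool if p not in used]
    if not free:
        free = [p for p in conserved + nonconserved if p not in used]
    if not free:
        raise ValueError(
            "more variants requested than available positions; "
            "increase mean_length or lower n_variants_per_protein"
        )
    return free[rng.integers(len(free))]


def generate_benchmark(config: SimulationConfig) -> SyntheticBenchmark:
    """Generate proteins, MSAs, ontology, annotations and labeled variants.

    The pathogenic variant count is exactly
    ``round(fraction_pathogenic * n_total)``: proteins are filled with
    pathogenic variants in order until the quota is spent (one boundary
    protein may carry both classes), which concentrates each class in
    near-pure proteins so the annotation skew has a protein-level class
    to attach to.
    """
    (rng_seq, rng_msa, rng_var, rng_annot, rng_scales) = _streams(config.seed, 5)

    dag, pool_disease, pool_neutral = _make_ontology(config.n_go_terms)
    all_go = pool_disease + pool_neutral
    site_terms = [f"SITE:{i:04d}" for i in range(config.n_site_terms)]
    half_site = config.n_site_terms // 2
    site_disease, site_neutral = site_terms[:half_site], site_terms[half_site:]
    scales = _make_scales(rng_scales, config.n_scales)

    n_total = config.n_proteins * config.n_variants_per_protein
    n_path = int(round(config.fraction_pathogenic * n_total))

    proteins: Dict[str, ProteinRecord] = {}
    variants: List[VariantRecord] = []
    conserved_map: Dict[str, frozenset] = {}
    go_annotations: Dict[str, frozenset] = {}
    site_annotations: Dict[str, frozenset] = {}
    quota = n_path

    for i in range(config.n_proteins):
        pid = f"P{i + 1:05d}"
        length = max(40, int(rng_seq.poisson(config.mean_length)))
        sequence = "".join(AMINO_ACIDS[j] for j in rng_seq.integers(0, 20, length))
        n_cons = max(1, int(round(config.conserved_fraction * length)))
        conserved = frozenset(
            int(p) + 1
            for p in rng_msa.choice(length, size=n_cons, replace=False)
        )
        msa = _make_msa(rng_msa, sequence, config.msa_depth, conserved)

        # labels for this protein's variants
        n_here = config.n_variants_per_protein
        n_path_here = min(n_here, quota)
        quota -= n_path_here
        labels = [PATHOGENIC] * n_path_here + [BENIGN] * (n_here - n_path_here)

        cons_list = sorted(conserved)
        noncons_list = sorted(set(range(1, length + 1)) - conserved)
        used: set = set()
        for label in labels:
            pos = _pick_position(
                rng_var, label, config.conservation_effect,
                cons_list, noncons_list, used,
            )
            used.add(pos)
            ref = sequence[pos - 1]
            alt = _pick_alt(rng_var, ref, label, config.delta_effect)
            variants.append(VariantRecord(pid, pos, ref, alt, label))

        # annotations keyed to the protein's dominant class
        is_disease = n_path_here * 2 >= n_here
        go: set = set()
        if rng_annot.random() >= config.fraction_unannotated:
            own = pool_disease if is_disease else pool_neutral
            for _ in range(int(rng_annot.integers(3, 8))):
                if rng_annot.random() < config.go_skew:
                    go.add(own[rng_annot.integers(len(own))])
                else:
                    go.add(all_go[rng_annot.integers(len(all_go))])
        sites: set = set()
        if rng_annot.random() >= config.fraction_unannotated:
            own_s = site_disease if is_disease else site_neutral
            for _ in range(int(rng_annot.integers(1, 3))):
                if rng_annot.random() < config.go_skew:
                    sites.add(own_s[rng_annot.integers(len(own_s))])
                else:
                    sites.add(site_terms[rng_annot.integers(len(site_terms))])

        proteins[pid] = ProteinRecord(
            id=pid, sequence=sequence, go_terms=frozenset(go),
            site_terms=frozenset(sites), msa=msa,
        )
        conserved_map[pid] = conserved
        go_annotations[pid] = frozenset(go)
        site_annotations[pid] = frozenset(sites)

    return SyntheticBenchmark(
        proteins=proteins,
        variants=variants,
        ontology=dag,
        go_annotations=go_annotations,
        site_annotations=site_annotations,
        scales=scales,
        conserved_columns=conserved_map,
        config=config,
    )


def null_benchmark(config: SimulationConfig) -> SyntheticBenchmark:
    """Same generator with every effect zeroed: labels carry no signal."""
    null_config = replace(
        config, conservation_effect=0.0, delta_effect=0.0, go_skew=0.0
    )
    return generate_benchmark(null_config)


# ---------------------------------------------------------------------------
# On-disk form: the exact formats the pipeline readers consume.


def write_benchmark(benchmark: SyntheticBenchmark, outdir) -> None:
    """Write FASTA / aligned FASTA / OBO / TSV files into ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    msa_dir = os.path.join(outdir, "msa")
    os.makedirs(msa_dir, exist_ok=True)

    with open(os.path.join(outdir, "proteins.fasta"), "w") as fh:
        for pid, p in sorted(benchmark.proteins.items()):
            fh.write(f">{pid}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i:i + 60] + "\n")

    for pid, p in sorted(benchmark.proteins.items()):
        if p.msa is None:
            continue
        with open(os.path.join(msa_dir, f"{pid}.fasta"), "w") as fh:
            for j, row in enumerate(p.msa):
                name = pid if j == 0 else f"{pid}_hom{j}"
                fh.write(f">{name}\n{row}\n")

    with open(os.path.join(outdir, "variants.tsv"), "w") as fh:
        fh.write("protein_id\tposition\tref_aa\talt_aa\tlabel\n")
        for v in benchmark.variants:
            lab = v.label if v.label != "unlabeled" else "."
            fh.write(f"{v.protein_id}\t{v.position}\t{v.ref_aa}\t{v.alt_aa}\t{lab}\n")

    with open(os.path.join(outdir, "ontology.obo"), "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for term in sorted(benchmark.ontology.parents):
            fh.write(f"\n[Term]\nid: {term}\nname: synthetic term {term}\n")
            for parent in sorted(benchmark.ontology.parents[term]):
                fh.write(f"is_a: {parent} ! parent\n")

    for fname, table in (
        ("go_annotations.tsv", benchmark.go_annotations),
        ("site_annotations.tsv", benchmark.site_annotations),
    ):
        with open(os.path.join(outdir, fname), "w") as fh:
            fh.write("protein_id\tterm_id\n")
            for pid in sorted(table):
                for term in sorted(table[pid]):
                    fh.write(f"{pid}\t{term}\n")

    with open(os.path.join(outdir, "aaindex.txt"), "w") as fh:
        order = "ARNDCQEGHILKMFPSTWVY"
        for s in benchmark.scales:
            fh.write(f"H {s.accession}\nD {s.description}\n")
            fh.write("I    A/L     R/K     N/M     D/F     C/P     Q/S"
                     "     E/T     G/W     H/Y     I/V\n")
            row1 = "".join(f"{s.values[aa]:8.3f}" for aa in order[:10])
            row2 = "".join(f"{s.values[aa]:8.3f}" for aa in order[10:])
            fh.write(f" {row1}\n {row2}\n//\n")
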