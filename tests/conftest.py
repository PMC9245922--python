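import numpy as np
import pytest

from varitol.core import BENIGN, PATHOGENIC, ProteinRecord, VariantRecord
from varitol.simulate import SimulationConfig, generate_benchmark


@pytest.fixture(scope="session")
def small_benchmark():
    """A 40-protein strong-signal benchmark shared across tests."""
    return generate_benchmark(SimulationConfig(n_proteins=40, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_variants(n_proteins, per_protein, n_pathogenic, seed=0):
    """Labeled variants over synthetic proteins, first ones pathogenic."""
    rng = np.random.default_rng(seed)
    variants = []
    k = 0
    for i in range(n_proteins):
        pid = f"P{i:04d}"
        for j in range(per_protein):
            label = PATHOGENIC if k < n_pathogenic else BENIGN
            ref, alt = "A", "CDEFGHIK"[int(rng.integers(8))]
            variants.append(VariantRecord(pid, j + 1, ref, alt, label))
            k += 1
    return variants


@pytest.fixture
def aaindex_file(tmp_path):
    """Three AAindex1 records, one incomplete (NA entries).

    The first record is the Kyte-Doolittle hydropathy index with its
    published values.
    """
    text = """\
H KYTJ820101
D Hydropathy index (Kyte-Doolittle, 1982)
R LIT:0816048b PMID:7108955
A Kyte, J. and Doolittle, R.F.
T A simple method for displaying the hydropathic character of a protein
J J. Mol. Biol. 157, 105-132 (1982)
C Scale correlations omitted
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.800  -4.500  -3.500  -3.500   2.500  -3.500  -3.500  -0.400  -3.200   4.500
    3.800  -3.900   1.900   2.800  -1.600  -0.800  -0.700  -0.900  -1.300   4.200
//
H FAKE000001
D An incomplete synthetic scale with missing values
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.000      NA   2.000   3.000   4.000   5.000   6.000   7.000   8.000   9.000
    1.000   2.000      NA   3.000   4.000   5.000   6.000   7.000   8.000   9.000
//
H FAKE000002
D A complete synthetic scale
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.100   0.200   0.300   0.400   0.500   0.600   0.700   0.800   0.900   1.000
    1.100   1.200   1.300   1.400   1.500   1.600   1.700   1.800   1.900   2.000
//
"""
    path = tmp_path / "aaindex1.txt"
    path.write_text(text)
    return path
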