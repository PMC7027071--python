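import io
import logging

import numpy as np
import pytest

from conscluster.conservation import read_fasta_msa
from conscluster.synthetic import (
    SyntheticComplexSpec,
    generate_complex,
    generate_msa,
)

logging.getLogger("conscluster").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def clustered_complex():
    """One deterministic synthetic complex with clustered conservation."""
    return generate_complex(SyntheticComplexSpec(seed=42, conservation_mode="CLUSTERED"))


@pytest.fixture(scope="session")
def clustered_msa(clustered_complex):
    syn = clustered_complex
    text = generate_msa(syn.sequence, syn.conserved_positions,
                        syn.spec.n_msa_rows, syn.spec.rngs()["msa"])
    return read_fasta_msa(io.StringIO(text))


@pytest.fixture(scope="session")
def small_complex():
    """Smaller complex for patch-level tests."""
    return generate_complex(
        SyntheticComplexSpec(seed=7, n_protein_residues=100, conservation_mode="SCATTERED"))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# --- tiny hand-written PDB fixtures (text, written to tmp_path by tests)

PDB_THREE_RES = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
TER
ATOM      4  P     U R   1       0.000   8.000   0.000  1.00  0.00           P
TER
END
"""

# one CB atom with two conformers: A at x=1 (occ 0.60), B at x=2 (occ 0.40)
PDB_ALTLOC = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CB AALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      3  CB BALA A   1       2.000   0.000   0.000  0.40  0.00           C
TER
END
"""


@pytest.fixture()
def pdb_three_res(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(PDB_THREE_RES)
    return p


@pytest.fixture()
def pdb_altloc(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(PDB_ALTLOC)
    return p
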