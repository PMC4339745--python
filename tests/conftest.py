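import numpy as np
import pytest

from pcalign import FixtureSpec, generate_synthetic_interface
from pcalign.interface_extract import Interface, InterfaceResidue
from pcalign.chem_classes import classify_residue

# hand-written minimal PDB: two chains, four residues with full side chains
ATOMIC_PDB = """\
ATOM      1  N   SER A   1       0.000   1.400   0.000  1.00  0.00           N
ATOM      2  CA  SER A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   SER A   1       1.400   0.000   0.000  1.00  0.00           C
ATOM      4  O   SER A   1       2.100   1.000   0.000  1.00  0.00           O
ATOM      5  OG  SER A   1       0.000   0.000   1.500  1.00  0.00           O
ATOM      6  N   LYS A   2       3.800   1.400   0.000  1.00  0.00           N
ATOM      7  CA  LYS A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      8  C   LYS A   2       5.200   0.000   0.000  1.00  0.00           C
ATOM      9  O   LYS A   2       5.900   1.000   0.000  1.00  0.00           O
ATOM     10  NZ  LYS A   2       3.800   0.000   2.500  1.00  0.00           N
TER
ATOM     11  N   GLU B   5       0.000   1.400   5.000  1.00  0.00           N
ATOM     12  CA  GLU B   5       0.000   0.000   5.000  1.00  0.00           C
ATOM     13  C   GLU B   5       1.400   0.000   5.000  1.00  0.00           C
ATOM     14  O   GLU B   5       2.100   1.000   5.000  1.00  0.00           O
ATOM     15  OE1 GLU B   5       0.000   0.000   3.600  1.00  0.00           O
ATOM     16  N   PHE B   6       3.800   1.400   5.000  1.00  0.00           N
ATOM     17  CA  PHE B   6       3.800   0.000   5.000  1.00  0.00           C
ATOM     18  C   PHE B   6       5.200   0.000   5.000  1.00  0.00           C
ATOM     19  O   PHE B   6       5.900   1.000   5.000  1.00  0.00           O
ATOM     20  CZ  PHE B   6       3.800   0.000   3.400  1.00  0.00           C
TER
END
"""

MSE_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
HETATM    2  CA  MSE A   2       3.800   0.000   0.000  1.00  0.00           C
HETATM    3 SE   MSE A   2       3.800   0.000   2.000  1.00  0.00          SE
ATOM      4  CA  ALA A   3       7.600   0.000   0.000  1.00  0.00           C
TER
END
"""

ALTLOC_PDB = """\
ATOM      1  CA ASER A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BSER A   1       9.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA AALA A   2       3.800   0.000   0.000  0.50  0.00           C
ATOM      4  CA BALA A   2       9.000   9.000   0.000  0.50  0.00           C
TER
END
"""


@pytest.fixture
def atomic_pdb(tmp_path):
    p = tmp_path / "atomic.pdb"
    p.write_text(ATOMIC_PDB)
    return p


@pytest.fixture
def ca_only_pdb(tmp_path):
    lines = [l for l in ATOMIC_PDB.splitlines() if l.startswith(("TER", "END")) or " CA " in l]
    p = tmp_path / "ca_only.pdb"
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture
def mse_pdb(tmp_path):
    p = tmp_path / "mse.pdb"
    p.write_text(MSE_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


@pytest.fixture
def small_interface():
    return generate_synthetic_interface(FixtureSpec(n_per_fragment=10, seed=1))


@pytest.fixture
def medium_interface():
    return generate_synthetic_interface(FixtureSpec(n_per_fragment=20, seed=1))


def toy_interface(coords_a, coords_b, aas_a=None, aas_b=None, contacts=None):
    """Build an Interface directly from coordinates (for unit tests).

    Contact map defaults to all inter-fragment pairs in contact so the
    Interface invariants hold for arbitrary geometry.
    """
    na, nb = len(coords_a), len(coords_b)
    aas_a = aas_a or ["A"] * na
    aas_b = aas_b or ["A"] * nb
    residues = [
        InterfaceResidue(("A", k + 1, "", aa), np.asarray(c, dtype=float),
                         classify_residue(aa), "A")
        for k, (c, aa) in enumerate(zip(coords_a, aas_a))
    ] + [
        InterfaceResidue(("B", k + 1, "", aa), np.asarray(c, dtype=float),
                         classify_residue(aa), "B")
        for k, (c, aa) in enumerate(zip(coords_b, aas_b))
    ]
    n = na + nb
    if contacts is None:
        contacts = np.zeros((n, n), dtype=bool)
        contacts[:na, na:] = True
        contacts[na:, :na] = True
    return Interface(id="toy", residues=residues, contacts=np.asarray(contacts, dtype=bool))
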