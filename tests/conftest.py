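import numpy as np
import pytest

from rnaqa.network import ModelConfig
from rnaqa.structure_io import Atom, Nucleotide, RNAStructure
from rnaqa.synthetic import make_native


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


def toy_structure(rng: np.random.Generator, L: int, atoms_per_nt: int = 3,
                  box: float = 12.0) -> RNAStructure:
    """Random multi-atom toy for lDDT oracle tests (no anchor requirements)."""
    names = ["C4'", "P", "N1", "C1'", "O3'"]
    nts = []
    for i in range(L):
        center = rng.uniform(-box, box, 3)
        atoms = {}
        for name in names[:atoms_per_nt]:
            atoms[name] = Atom(name, center + rng.normal(0.0, 1.5, 3))
        nts.append(Nucleotide(i + 1, "ACGU"[i % 4], atoms))
    return RNAStructure(f"toy{L}", "A", nts)


@pytest.fixture(scope="session")
def helix20():
    return make_native(20, seed=3, geometry="helix")


@pytest.fixture(scope="session")
def coil16():
    return make_native(16, seed=5, geometry="coil")


@pytest.fixture(scope="session")
def tiny_config():
    return ModelConfig(n_layers=2, n_heads=2, hidden=16,
                       n_query_points=2, n_value_points=2, K=6)


MINI_PDB = """\
ATOM      1  P     A A   1      10.000   0.000   0.000  1.00  0.00           P
ATOM      2  C4'   A A   1      11.500   1.200   0.500  1.00  0.00           C
ATOM      3  N9    A A   1      12.800   0.400   1.900  1.00  0.00           N
ATOM      4  H5'   A A   1      11.000   2.000   2.000  1.00  0.00           H
ATOM      5  P     C A   2      14.000   2.000   2.500  1.00  0.00           P
ATOM      6  C4'   C A   2      15.400   3.300   3.000  1.00  0.00           C
ATOM      7  N1    C A   2      16.800   2.500   4.200  1.00  0.00           N
ATOM      8  P     G A   3      18.000   4.000   5.000  1.00  0.00           P
ATOM      9  C4'   G A   3      19.300   5.100   5.600  1.00  0.00           C
ATOM     10  N9    G A   3      20.700   4.300   6.800  1.00  0.00           N
END
"""


@pytest.fixture
def mini_pdb(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINI_PDB)
    return path
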