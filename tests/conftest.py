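import numpy as np
import pytest

from accref.structures import ProteinModel, Residue
from accref.synthetic import DecoySpec, make_decoys, make_native


TINY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.988  -0.773  -1.199  1.00  0.00           C
ATOM      6  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       3.970   2.846   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2       5.480   2.705   0.100  1.00  0.00           C
ATOM      9  O   GLY A   2       6.030   1.610   0.200  1.00  0.00           O
ATOM     10  N   SER A   3       6.150   3.850   0.050  1.00  0.00           N
ATOM     11  CA ASER A   3       7.600   3.900   0.100  0.70  0.00           C
ATOM     12  CA BSER A   3       7.700   4.000   0.200  0.30  0.00           C
ATOM     13  C   SER A   3       8.200   5.290   0.150  1.00  0.00           C
ATOM     14  O   SER A   3       7.530   6.320   0.100  1.00  0.00           O
ATOM     15  CB  SER A   3       8.150   3.100  -1.080  1.00  0.00           C
TER
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    """3-residue PDB with a GLY and an altloc pair on residue 3's CA."""
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return str(path)


@pytest.fixture(scope="session")
def helix_spec():
    return DecoySpec(n_residues=30, topology="helix_bundle", seed=101)


@pytest.fixture(scope="session")
def native30(helix_spec):
    return make_native(helix_spec)


@pytest.fixture(scope="session")
def decoys30(native30, helix_spec):
    """Five decoys of the 30-residue native at increasing perturbation."""
    return make_decoys(native30, 5, [4.0, 8.0, 15.0, 25.0, 40.0],
                       seed=102, spec=helix_spec)


def make_pair_model(cb_distance: float) -> ProteinModel:
    """Two-residue model whose CB-CB distance is exactly ``cb_distance``."""
    def residue(offset, num):
        atoms = {
            "N": np.array([0.0, 1.4, 0.0]) + offset,
            "CA": np.array([0.0, 0.0, 0.0]) + offset,
            "C": np.array([1.4, -0.5, 0.0]) + offset,
            "CB": np.array([0.0, 0.0, 0.0]) + offset,
        }
        return Residue("A", atoms, num)
    r1 = residue(np.zeros(3), 1)
    r2 = residue(np.array([cb_distance, 0.0, 0.0]), 2)
    return ProteinModel("A", [r1, r2])


@pytest.fixture
def pair_model_factory():
    return make_pair_model


def random_rigid(rng: np.random.Generator):
    """Random proper rotation + translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    trans = rng.normal(scale=20.0, size=3)
    return rot, trans


@pytest.fixture
def rigid_factory():
    return random_rigid
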