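"""Shared fixtures: point-atom form factors, toy structures, PDB texts."""

import numpy as np
import pytest

from sascov import FormFactorModel, Structure, point_model
from sascov.synthetic import ToySpec, make_toy_structure

THREE_ATOM_PDB = """\
HEADER    TEST STRUCTURE
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 20.00           C
ATOM      3  O   ALA A   1       2.100   1.300   0.500  1.00 78.96           O
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       0.000   4.200   0.000  1.00  0.00           C
ENDMDL
END
"""

WATER_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def point_ff() -> FormFactorModel:
    return point_model()


@pytest.fixture
def cm_ff() -> FormFactorModel:
    return FormFactorModel()


@pytest.fixture
def two_point_atoms() -> Structure:
    """Two point atoms 5 A apart: I(q) = 2 (1 + sinc(5q)) with f = 1."""
    return Structure(elements=["X", "X"], coords=[[0, 0, 0], [5.0, 0, 0]])


@pytest.fixture
def cloud5() -> Structure:
    """5-atom random cloud used by the covariance oracle tests."""
    return make_toy_structure(
        ToySpec(kind="random-cloud", n_atoms=5, scale=8.0, seed=42, element="X")
    )


@pytest.fixture
def cloud10() -> Structure:
    return make_toy_structure(
        ToySpec(kind="random-cloud", n_atoms=10, scale=8.0, tau=0.5, seed=3, element="X")
    )


@pytest.fixture
def pdb_file(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_ATOM_PDB)
    return p


@pytest.fixture
def two_model_file(tmp_path):
    p = tmp_path / "two_model.pdb"
    p.write_text(TWO_MODEL_PDB)
    return p


@pytest.fixture
def water_file(tmp_path):
    p = tmp_path / "water.pdb"
    p.write_text(WATER_ONLY_PDB)
    return p


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation matrix via QR."""
    m, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(m) < 0:
        m[:, 0] = -m[:, 0]
    return m
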