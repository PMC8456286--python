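import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    max_examples=30,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


TOY_PDB = """\
HEADER    TOY PEPTIDE
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.300   2.400   0.000  1.00  0.00           O
ATOM      5  CA  GLY A   2       3.500   1.600   0.500  1.00  0.00           C
ATOM      6  N   GLY A   2       4.200   0.500   1.200  1.00  0.00           N
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       0.000   0.000   9.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   9.000  1.00  0.00           C
ATOM      3  CA  SER A   3       7.600   0.000   9.000  1.00  0.00           C
ATOM      4  CA  THR A   4      11.400   0.000   9.000  1.00  0.00           C
ENDMDL
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture
def two_model_pdb(tmp_path):
    path = tmp_path / "two_model.pdb"
    path.write_text(TWO_MODEL_PDB)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation_matrix(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()
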