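import numpy as np
import pytest

from xltrap.synthetic import SyntheticComplexSpec, make_toy_complex, random_coil

THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       2.000  -1.300   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       3.400  -1.500   0.000  1.00  0.00           C
ATOM      6  N   SER A   3       4.000  -2.800   0.500  1.00  0.00           N
ATOM      7  CA  SER A   3       5.400  -3.000   0.500  1.00  0.00           C
ATOM      8  CB  SER A   3       6.000   1.400   0.000  1.00  0.00           C
TER
END
"""


@pytest.fixture(scope="session")
def three_residue_pdb() -> str:
    return THREE_RESIDUE_PDB


@pytest.fixture(scope="session")
def toy_complex():
    """A seeded two-body complex with 12 planted crosslink restraints."""
    return make_toy_complex(SyntheticComplexSpec(seed=42))


@pytest.fixture(scope="session")
def coil_pair():
    """Two elongated pseudo-protein coils, well separated: bodies with
    distinct principal axes for orientation analytics."""
    gen = np.random.default_rng(77)
    rec = random_coil(40, gen, chain="R")
    mob = random_coil(40, gen, chain="A")
    mob = mob.with_coords(mob.coords + np.array([0.0, 30.0, 0.0]))
    return rec, mob


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
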