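import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))

from rnasphere.fixtures import HelixParams, PerturbationSpec, generate_helix, perturb


MINIMAL_PDB = """\
ATOM      1  P     G A   1      10.000   4.000   1.000  1.00  0.00           P
ATOM      2  C1'   G A   1      12.500   5.200   2.100  1.00  0.00           C
ATOM      3  O3'   G A   1      11.100   6.800   0.500  1.00  0.00           O
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


@pytest.fixture
def helix10():
    return generate_helix(HelixParams(n_residues=10, seed=11))


@pytest.fixture
def helix20():
    return generate_helix(HelixParams(n_residues=20, seed=7))


@pytest.fixture
def helix30():
    return generate_helix(HelixParams(n_residues=30, seed=5))


@pytest.fixture
def noisy_decoy(helix20):
    return perturb(
        helix20, PerturbationSpec(kind="gaussian_noise", magnitude=1.0, seed=42)
    )
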