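import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


ALA_GLY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.004   1.423   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.397   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.010  -0.765  -1.206  1.00  0.00           C
ATOM      6  N   GLY A   2       3.330   1.535   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       3.980   2.833   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2       5.493   2.694   0.000  1.00  0.00           C
ATOM      9  O   GLY A   2       6.023   1.583   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def ala_gly_text():
    return ALA_GLY_PDB


@pytest.fixture
def ala_gly(ala_gly_text):
    from kelchdyn.structure_io import read_structure
    return read_structure(ala_gly_text)


@pytest.fixture(scope="session")
def template():
    from kelchdyn.beta_order import ideal_antiparallel_template
    return ideal_antiparallel_template()


@pytest.fixture(scope="session")
def sheet_4x6():
    from kelchdyn.synthetic_data import make_sheet
    return make_sheet(4, 6)


@pytest.fixture(scope="session")
def random_structure_20():
    """A 20-residue random coil used for oracle comparisons."""
    from kelchdyn.synthetic_data import make_coil
    return make_coil(20, np.random.default_rng(42))
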