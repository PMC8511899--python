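import numpy as np
import pytest

from tunnelflex import default_region_map
from tunnelflex.synthetic import make_bfactor_fixture, make_complex_fixture

ONE_RESIDUE_PDB = """\
ATOM      1  N   ALA A  22      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A  22      11.639   6.071  -5.147  1.00 12.50           C
ATOM      3  C   ALA A  22      12.755   7.096  -4.952  1.00 14.25           C
END
"""


@pytest.fixture(scope="session")
def region_map():
    return default_region_map()


@pytest.fixture(scope="session")
def interacting24(region_map):
    return region_map.interacting24


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def complex_structure():
    """Three-sugar glycan bound over a catalytic triad with two exact contacts."""
    return make_complex_fixture(
        contacts=[
            ("ARG", 215, "NH1", 0, "O6B", 2.9),
            ("TYR", 38, "OH", 1, "O2", 2.8),
        ]
    )


@pytest.fixture()
def uniform_structure():
    return make_bfactor_fixture(b_profile=10.0, n_residues=5)
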