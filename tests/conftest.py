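import numpy as np
import pytest

from cnascreen import (
    CORE_REGIONS,
    FixtureSpec,
    KNOWN_TRIADS,
    TABLE_SPLITS,
    make_parent_domain,
    make_two_strand_parallel,
    plant_triad,
)

MINIMAL_GLY_PDB = """\
ATOM      1  N   GLY A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       2.400   2.100   3.200  1.00  0.00           C
ATOM      3  C   GLY A   1       3.100   1.000   2.500  1.00  0.00           C
ATOM      4  O   GLY A   1       2.700   0.200   1.700  1.00  0.00           O
END
"""


@pytest.fixture
def gly_pdb_text():
    return MINIMAL_GLY_PDB


@pytest.fixture
def two_strand_spec():
    return FixtureSpec(n_residues=8, hbond_distance=2.9, seed=11)


@pytest.fixture
def two_strand(two_strand_spec):
    return make_two_strand_parallel(two_strand_spec)


@pytest.fixture
def planted(two_strand, two_strand_spec):
    return plant_triad(two_strand, two_strand_spec)


@pytest.fixture
def parent_4oq1():
    """Synthetic stand-in parent for the 4oq1 D2 domain (author numbering)."""
    return make_parent_domain(TABLE_SPLITS["4oq1"], *KNOWN_TRIADS["4oq1"],
                              header_id="synthetic-4oq1")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
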