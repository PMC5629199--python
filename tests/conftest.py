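"""Shared fixtures: small structures, coupling tables, funnel chains."""

import numpy as np
import pytest

from ecsampler.fixtures import FunnelChainSpec, generate_msm


MINI_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   SER A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  SER A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      7  CB  SER A   2       5.504   2.693   0.100  1.00  0.00           C
ATOM      8  OG  SER A   2       6.122   3.962   0.200  1.00  0.00           O
ATOM      9  C   SER A   2       3.600   3.700   1.200  1.00  0.00           C
ATOM     10  O   SER A   2       3.200   3.200   2.250  1.00  0.00           O
END
"""


@pytest.fixture
def mini_pdb(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINI_PDB)
    return path


@pytest.fixture
def coupling_csv(tmp_path):
    path = tmp_path / "ec.csv"
    path.write_text("i,j,score\n1,5,0.9\n2,7,0.3\n")
    return path


@pytest.fixture
def funnel5():
    """Tiny 5-state funnel chain with exactly known stationary distribution."""
    return generate_msm(FunnelChainSpec(n_states=5, barrier=2.0, seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
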