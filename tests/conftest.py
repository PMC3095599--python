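import numpy as np
import pytest

from enzgraft import fixtures as fx
from enzgraft.cst import parse_cstfile
from enzgraft.matcher import MatchConfig, match_structure, run_matcher

# the worked constraint-block example used throughout the cstfile tests
EXAMPLE_BLOCK = """
CST::BEGIN
  TEMPLATE::   ATOM_MAP: 1 atom_name: C1 C2 O2
  TEMPLATE::   ATOM_MAP: 1 residue3: 1n1
  TEMPLATE::   ATOM_MAP: 2 atom_type: OOC,
  TEMPLATE::   ATOM_MAP: 2 residue1: ED
  CONSTRAINT:: distanceAB:    3.06   0.2  100.  0    0
  CONSTRAINT:: angle_A:      73.60  10.0   80.0 360. 1
  CONSTRAINT:: angle_B:     120.00  15.0   80.0 360. 1
  CONSTRAINT:: torsion_A:  -101.20  15.0   60.0 360. 1
  CONSTRAINT:: torsion_AB:  180.00  90.0    0.00 360. 3
  CONSTRAINT:: torsion_B:   180.00  15.0    0.00 360. 1
CST::END
"""


@pytest.fixture(scope="session")
def example_theozyme():
    t = parse_cstfile(EXAMPLE_BLOCK)
    t.validate()
    return t


@pytest.fixture(scope="session")
def example_block(example_theozyme):
    return example_theozyme.blocks[0]


@pytest.fixture(scope="session")
def tim_theozyme():
    return fx.make_theozyme_tim()


@pytest.fixture(scope="session")
def ligand():
    return fx.make_dhap_ligand()


@pytest.fixture(scope="session")
def scaffold():
    return fx.make_toy_scaffold(seed=1)


@pytest.fixture(scope="session")
def planted(scaffold):
    return fx.plant_site(scaffold, seed=1)


@pytest.fixture(scope="session")
def planted_matches(planted):
    matches, diag = run_matcher(planted.scaffold, planted.theozyme,
                                planted.positions, planted.ligand)
    return matches, diag


@pytest.fixture(scope="session")
def match_model(planted, planted_matches):
    matches, _ = planted_matches
    return match_structure(matches[0], planted.scaffold, planted.ligand)
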