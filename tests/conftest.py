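"""Shared fixtures: tiny hand-written structure files and random profiles."""

import numpy as np
import pytest
from hypothesis import settings

from fodm.structure_io import EffectiveAtomSet, ResidueId

# property tests replay the same example sequence on every run
settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

# Two alanine-like residues, two atoms each, hand-written fixed-column PDB.
TWO_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.000   0.000   0.000  1.00  0.00           C
ATOM      3  N   GLY A   2       4.000   1.000   0.000  1.00  0.00           N
ATOM      4  CA  GLY A   2       4.000   3.000   0.000  1.00  0.00           C
END
"""

# The same two residues as a minimal mmCIF.
TWO_RESIDUE_CIF = """\
data_test
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM 1 N N . ALA A 1 1 ? 0.000 0.000 0.000 1.00 0.00 1 A 1
ATOM 2 C CA . ALA A 1 1 ? 2.000 0.000 0.000 1.00 0.00 1 A 1
ATOM 3 N N . GLY A 1 2 ? 4.000 1.000 0.000 1.00 0.00 2 A 1
ATOM 4 C CA . GLY A 1 2 ? 4.000 3.000 0.000 1.00 0.00 2 A 1
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       9.000   9.000   9.000  1.00  0.00           C
ATOM      2  CA  GLY A   2      12.800   9.000   9.000  1.00  0.00           C
ENDMDL
END
"""

# Two cysteines with SG atoms 2.04 Å apart plus one far-away cysteine.
# A few glycines spread the cloud so a 3D Gaussian field is fittable.
DISULFIDE_PDB = """\
ATOM      1  CA  CYS A  10       0.000   0.500   0.000  1.00  0.00           C
ATOM      2  SG  CYS A  10       1.000   0.000   0.000  1.00  0.00           S
ATOM      3  CA  GLY A  20       2.000   4.000   1.000  1.00  0.00           C
ATOM      4  CA  GLY A  30       1.000   2.000   5.000  1.00  0.00           C
ATOM      5  CA  CYS A  40       4.000   0.300   0.000  1.00  0.00           C
ATOM      6  SG  CYS A  40       3.040   0.000   0.000  1.00  0.00           S
ATOM      7  CA  GLY A  60       6.000   5.000   3.000  1.00  0.00           C
ATOM      8  CA  CYS A  80      30.000   2.000   1.000  1.00  0.00           C
ATOM      9  SG  CYS A  80      31.000   2.000   1.000  1.00  0.00           S
END
"""


@pytest.fixture
def two_residue_pdb(tmp_path):
    p = tmp_path / "two.pdb"
    p.write_text(TWO_RESIDUE_PDB)
    return p


@pytest.fixture
def two_residue_cif(tmp_path):
    p = tmp_path / "two.cif"
    p.write_text(TWO_RESIDUE_CIF)
    return p


@pytest.fixture
def two_model_pdb(tmp_path):
    p = tmp_path / "models.pdb"
    p.write_text(TWO_MODEL_PDB)
    return p


@pytest.fixture
def disulfide_pdb(tmp_path):
    p = tmp_path / "ss.pdb"
    p.write_text(DISULFIDE_PDB)
    return p


def make_atoms(positions, names=None, chain="A"):
    """EffectiveAtomSet from raw coordinates (helper for numeric tests)."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if names is None:
        names = ["ALA"] * n
    rids = [ResidueId(chain, i + 1) for i in range(n)]
    return EffectiveAtomSet(rids, positions, list(names))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
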