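"""Shared fixtures: tiny hand-written PDB texts and structure builders."""

from __future__ import annotations

import numpy as np
import pytest

from dockeval.structures import AtomRecord, ResidueKey, StructureModel

# A deliberately messy two-chain complex: 3 residues in chain A (one with
# A/B altlocs on CB, one hydrogen to drop), 2 residues in chain B, a 3-atom
# ligand in chain A and waters in both chains.
TWO_CHAIN_PDB = """\
ATOM      1  N   ALA A   1      11.000   6.000  -6.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      12.000   6.500  -6.200  1.00  0.00           C
ATOM      3  C   ALA A   1      13.000   6.000  -5.500  1.00  0.00           C
ATOM      4  O   ALA A   1      13.500   5.000  -5.800  1.00  0.00           O
ATOM      5  CB AALA A   1      12.200   8.000  -6.300  0.40  0.00           C
ATOM      6  CB BALA A   1      12.300   8.100  -6.400  0.60  0.00           C
ATOM      7  H   ALA A   1      11.100   5.500  -6.100  1.00  0.00           H
ATOM      8  N   GLY A   2      13.400   6.700  -4.500  1.00  0.00           N
ATOM      9  CA  GLY A   2      14.400   6.300  -3.600  1.00  0.00           C
ATOM     10  C   GLY A   2      15.500   7.200  -3.400  1.00  0.00           C
ATOM     11  O   GLY A   2      15.600   8.300  -3.900  1.00  0.00           O
ATOM     12  N   LEU A   3      16.400   6.700  -2.600  1.00  0.00           N
ATOM     13  CA  LEU A   3      17.600   7.400  -2.200  1.00  0.00           C
ATOM     14  C   LEU A   3      18.700   6.500  -1.800  1.00  0.00           C
ATOM     15  O   LEU A   3      18.600   5.300  -2.000  1.00  0.00           O
ATOM     16  CB  LEU A   3      17.300   8.300  -1.000  1.00  0.00           C
TER      17
ATOM     18  N   SER B   1       1.000   1.000   1.000  1.00  0.00           N
ATOM     19  CA  SER B   1       2.200   1.400   1.400  1.00  0.00           C
ATOM     20  C   SER B   1       3.300   0.700   1.000  1.00  0.00           C
ATOM     21  O   SER B   1       3.400  -0.400   1.400  1.00  0.00           O
ATOM     22  N   THR B   2       4.200   1.300   0.300  1.00  0.00           N
ATOM     23  CA  THR B   2       5.400   0.800  -0.300  1.00  0.00           C
ATOM     24  C   THR B   2       6.500   1.800  -0.300  1.00  0.00           C
ATOM     25  O   THR B   2       6.500   2.800  -1.000  1.00  0.00           O
HETATM   26  C1  LIG A 101      14.000   7.000  -4.000  1.00  0.00           C
HETATM   27  O1  LIG A 101      14.800   7.800  -4.400  1.00  0.00           O
HETATM   28  N1  LIG A 101      13.200   7.400  -3.100  1.00  0.00           N
HETATM   29  O   HOH A 201      10.000  10.000  10.000  1.00  0.00           O
HETATM   30  O   HOH A 202      10.500  10.500  10.500  1.00  0.00           O
HETATM   31  O   HOH B 203      -5.000  -5.000  -5.000  1.00  0.00           O
HETATM   32  O   HOH B 204      -5.500  -5.500  -5.500  1.00  0.00           O
HETATM   33  O   HOH B 205      -6.000  -6.000  -6.000  1.00  0.00           O
END
"""

THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.300   1.600   0.100  1.00  0.00           N
ATOM      5  CA  GLY A   2       4.000   2.900   0.200  1.00  0.00           C
ATOM      6  C   GLY A   2       5.500   2.800   0.100  1.00  0.00           C
ATOM      7  N   VAL A   3       6.200   3.900   0.000  1.00  0.00           N
ATOM      8  CA  VAL A   3       7.700   3.900   0.100  1.00  0.00           C
ATOM      9  C   VAL A   3       8.300   5.300   0.200  1.00  0.00           C
END
"""


@pytest.fixture
def two_chain_pdb(tmp_path):
    p = tmp_path / "complex.pdb"
    p.write_text(TWO_CHAIN_PDB)
    return p


@pytest.fixture
def three_residue_pdb(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_RESIDUE_PDB)
    return p


def build_structure(residue_atoms, structure_id="toy", kind="synthetic",
                    chain="A", ligands=None):
    """Hand-build a StructureModel.

    ``residue_atoms`` is a list of (residue_name, [(atom_name, element,
    (x, y, z)), ...]); residues are numbered 1..n in ``chain``.
    """
    residues = {}
    for num, (resname, atoms) in enumerate(residue_atoms, start=1):
        key = ResidueKey(chain_id=chain, residue_number=num, residue_name=resname)
        residues[key] = [AtomRecord(n, el, np.asarray(xyz, float)) for n, el, xyz in atoms]
    return StructureModel(structure_id=structure_id, kind=kind,
                          residues=residues, ligands=dict(ligands or {}))


def translate_structure(s, shift):
    """Copy of a structure with all atoms (and ligands) rigidly shifted."""
    return transform_structure(s, np.eye(3), shift)


def transform_structure(s, rotation, translation):
    """Copy of a structure with ``x -> R x + t`` applied to every atom."""
    rotation = np.asarray(rotation, float)
    translation = np.asarray(translation, float)
    residues = {
        key: [AtomRecord(r.atom_name, r.element, rotation @ r.coords + translation,
                         r.occupancy, r.altloc) for r in recs]
        for key, recs in s.residues.items()
    }
    ligands = {lid: pose.transformed(rotation, translation) for lid, pose in s.ligands.items()}
    return StructureModel(structure_id=s.structure_id + "-moved", kind=s.kind,
                          residues=residues, ligands=ligands)


def random_rotation(rng):
    """Uniform-ish random proper rotation from QR decomposition."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
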