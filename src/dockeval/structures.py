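"""Reading, cleaning and indexing protein structures and ligand poses.

The internal data model is deliberately small: a :class:`StructureModel` is an
ordered map from :class:`ResidueKey` to lists of heavy-atom records, plus any
extracted ligand poses.  Hydrogens are dropped at read time because every
downstream metric is defined over non-hydrogen atoms.  Residue numbering is
taken verbatim from the file (author numbering); correspondence between two
structures is established only through :func:`map_residues`, never by raw
number equality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import gemmi
import numpy as np
from Bio import Align
from Bio.SeqUtils import seq1

from .errors import (
    AmbiguousLigandError,
    EmptyStructureError,
    MappingError,
    StructureParseError,
    UnknownLigandError,
)

__all__ = [
    "BACKBONE_ATOMS",
    "WATER_RESNAMES",
    "STRUCTURE_KINDS",
    "AtomRecord",
    "ResidueKey",
    "LigandPose",
    "StructureModel",
    "read_structure",
    "read_ligand_pose",
    "clean_structure",
    "map_residues",
    "write_pdb",
]

#: Atom names that constitute the peptide backbone.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

#: Residue names treated as water during cleaning.
WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: Allowed provenance labels for a structure.
STRUCTURE_KINDS = ("experimental", "af2", "traditional", "synthetic")

_HYDROGEN = frozenset({"H", "D"})


@dataclass(frozen=True)
class ResidueKey:
    """Identity of one residue: chain, author number, insertion code, name.

    ``(chain_id, residue_number, insertion_code)`` uniquely identifies a
    residue within a structure; ``residue_name`` is carried along for
    sequence-aware mapping.
    """

    chain_id: str
    residue_number: int
    insertion_code: str = ""
    residue_name: str = ""

    def same_position(self, other: "ResidueKey") -> bool:
        return (
            self.chain_id == other.chain_id
            and self.residue_number == other.residue_number
            and self.insertion_code == other.insertion_code
        )


@dataclass
class AtomRecord:
    """One heavy atom: PDB atom name, element, coordinates in Angstrom."""

    atom_name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.atom_name!r}: coordinates must be a finite 3-vector")

    @property
    def is_backbone(self) -> bool:
        return self.atom_name in BACKBONE_ATOMS


@dataclass
class LigandPose:
    """A 3D heavy-atom conformation of a ligand.

    ``graph`` optionally ties the pose to a chemical graph
    (:class:`dockeval.ligands.MolGraph`) so that symmetry-corrected RMSDs can
    minimize over graph automorphisms.
    """

    ligand_id: str
    atom_names: list
    elements: list
    coords: np.ndarray
    graph: Optional[object] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("pose coordinates must be an (N, 3) array")
        if len(self.atom_names) != len(self.coords) or len(self.elements) != len(self.coords):
            raise ValueError("atom_names, elements and coords must have equal length")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LigandPose":
        """Return a copy with ``x -> R x + t`` applied to every atom."""
        return replace(self, coords=self.coords @ np.asarray(rotation).T + translation)

    def copy(self) -> "LigandPose":
        return replace(self, coords=self.coords.copy(), atom_names=list(self.atom_names),
                       elements=list(self.elements))


@dataclass
class StructureModel:
    """A labeled protein structure with residue/chain bookkeeping.

    ``residues`` holds polymer (ATOM-record) residues; ``hetero`` holds
    HETATM groups (waters, ligands, ions) until :func:`clean_structure`
    resolves them.  Both preserve file order (dicts are insertion ordered).
    """

    structure_id: str
    kind: str
    residues: dict = field(default_factory=dict)
    hetero: dict = field(default_factory=dict)
    ligands: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in STRUCTURE_KINDS:
            raise ValueError(f"kind must be one of {STRUCTURE_KINDS}, got {self.kind!r}")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def chain_ids(self) -> list:
        seen = dict.fromkeys(k.chain_id for k in self.residues)
        return list(seen)

    def atoms(self) -> Iterable:
        """Yield ``(ResidueKey, AtomRecord)`` over polymer residues."""
        for key, recs in self.residues.items():
            for rec in recs:
                yield key, rec

    def coords_array(self) -> np.ndarray:
        return np.array([rec.coords for _, rec in self.atoms()], dtype=float).reshape(-1, 3)

    def residue_coords(self, key: ResidueKey) -> np.ndarray:
        return np.array([rec.coords for rec in self.residues[key]], dtype=float).reshape(-1, 3)

    def one_letter_sequence(self) -> str:
        return "".join(seq1(k.residue_name, undef_code="X") for k in self.residues)

    def equals(self, other: "StructureModel", atol: float = 0.0) -> bool:
        """Structural equality: same residues, atom names and coordinates."""
        if list(self.residues) != list(other.residues):
            return False
        for key in self.residues:
            a, b = self.residues[key], other.residues[key]
            if [r.atom_name for r in a] != [r.atom_name for r in b]:
                return False
            if not np.allclose([r.coords for r in a], [r.coords for r in b], atol=atol):
                return False
        return set(self.ligands) == set(other.ligands)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_structure(path, kind: str = "experimental", structure_id: str | None = None) -> StructureModel:
    """Read a PDB file into a raw :class:`StructureModel`.

    All chains, hetero groups and alternate locations are preserved;
    hydrogens are dropped.  Use :func:`clean_structure` to reduce to the
    single ligand-bearing chain.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi raises RuntimeError with line info
        raise StructureParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models in file")
    model = StructureModel(structure_id=structure_id or path.stem, kind=kind)
    gm = st[0]
    n_atoms = 0
    for chain in gm:
        for res in chain:
            is_het = res.het_flag == "H"
            key = ResidueKey(
                chain_id=chain.name,
                residue_number=res.seqid.num,
                insertion_code=(res.seqid.icode or " ").strip(),
                residue_name=res.name,
            )
            recs = []
            for atom in res:
                if atom.element.name.upper() in _HYDROGEN:
                    continue
                recs.append(
                    AtomRecord(
                        atom_name=atom.name,
                        element=atom.element.name.upper() or "C",
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=atom.occ,
                        altloc=atom.altloc.replace("\x00", "").strip(),
                    )
                )
            if not recs:
                continue
            n_atoms += len(recs)
            target = model.hetero if is_het else model.residues
            if key in target:
                target[key].extend(recs)
            else:
                target[key] = recs
    if n_atoms == 0:
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records with heavy atoms")
    return model


def read_ligand_pose(path, ligand_id: str | None = None) -> LigandPose:
    """Read a ligand pose from an SDF/MOL coordinate block or a PDB file.

    Heavy atoms only; for SDF input the connectivity is parsed as written
    (no aromaticity re-perception) and attached as a chemical graph.
    """
    path = Path(path)
    if path.suffix.lower() in {".sdf", ".mol"}:
        from rdkit import Chem

        from .ligands import molgraph_from_rdkit

        mol = Chem.MolFromMolFile(str(path), sanitize=False, removeHs=False)
        if mol is None:
            raise StructureParseError(f"{path}: unreadable SDF/MOL block")
        conf = mol.GetConformer()
        keep = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() not in _HYDROGEN]
        coords = np.array([list(conf.GetAtomPosition(i)) for i in keep], dtype=float)
        elements = [mol.GetAtomWithIdx(i).GetSymbol() for i in keep]
        names = [f"{el}{i + 1}" for i, el in enumerate(elements)]
        graph = molgraph_from_rdkit(mol, heavy_indices=keep)
        return LigandPose(ligand_id or path.stem, names, elements, coords, graph=graph)
    s = read_structure(path, kind="synthetic")
    groups = {k: v for k, v in s.hetero.items() if k.residue_name not in WATER_RESNAMES}
    if ligand_id is not None:
        groups = {k: v for k, v in groups.items() if k.residue_name == ligand_id}
    if not groups:
        raise UnknownLigandError(f"{path}: no hetero group{f' {ligand_id!r}' if ligand_id else ''}")
    recs = [r for v in groups.values() for r in v]
    return LigandPose(
        ligand_id or next(iter(groups)).residue_name,
        [r.atom_name for r in recs],
        [r.element for r in recs],
        np.array([r.coords for r in recs]),
    )


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------

def _resolve_altlocs(recs: list) -> list:
    """Keep one atom per atom_name: highest occupancy, ties broken toward 'A'."""
    by_name: dict = {}
    for rec in recs:
        by_name.setdefault(rec.atom_name, []).append(rec)
    out = []
    for name, group in by_name.items():
        best = min(group, key=lambda r: (-r.occupancy, r.altloc or "A"))
        out.append(replace(best, altloc="", coords=best.coords.copy()))
    return out


def clean_structure(s: StructureModel, ligand_id: str) -> StructureModel:
    """Reduce to the single ligand-bearing chain, waters removed.

    Keeps only the protein chain that contains the named hetero group,
    removes all waters and all other hetero groups, resolves alternate
    locations (highest occupancy; ties toward altloc 'A'), and extracts the
    ligand as a :class:`LigandPose`.  Idempotent.
    """
    if ligand_id in s.ligands and not any(
        k.residue_name == ligand_id for k in s.hetero
    ):
        # already cleaned with respect to this ligand; re-apply chain filter only
        pose = s.ligands[ligand_id].copy()
        lig_chains = s.chain_ids[:1] or [""]
        chain = lig_chains[0]
        residues = {k: _resolve_altlocs(v) for k, v in s.residues.items() if k.chain_id == chain}
        return StructureModel(s.structure_id, s.kind, residues, {}, {ligand_id: pose})

    matches = {k: v for k, v in s.hetero.items()
               if k.residue_name == ligand_id and k.residue_name not in WATER_RESNAMES}
    if not matches:
        raise UnknownLigandError(f"{s.structure_id}: no hetero group named {ligand_id!r}")
    chains = sorted({k.chain_id for k in matches})
    if len(chains) > 1:
        raise AmbiguousLigandError(
            f"{s.structure_id}: ligand {ligand_id!r} appears in chains {chains}"
        )
    chain = chains[0]
    lig_keys = [k for k in matches if k.chain_id == chain]
    if len(lig_keys) > 1:
        warnings.warn(
            f"{s.structure_id}: {len(lig_keys)} copies of {ligand_id!r} in chain {chain}; "
            "keeping the first", stacklevel=2,
        )
        lig_keys = lig_keys[:1]
    lig_recs = _resolve_altlocs(matches[lig_keys[0]])
    pose = LigandPose(
        ligand_id,
        [r.atom_name for r in lig_recs],
        [r.element for r in lig_recs],
        np.array([r.coords for r in lig_recs]),
    )
    residues = {
        k: _resolve_altlocs(v) for k, v in s.residues.items() if k.chain_id == chain
    }
    return StructureModel(s.structure_id, s.kind, residues, {}, {ligand_id: pose})


# ---------------------------------------------------------------------------
# Residue correspondence
# ---------------------------------------------------------------------------

def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1.0
    al.mismatch_score = -1.0
    al.open_gap_score = -2.0
    al.extend_gap_score = -0.5
    return al


def map_residues(model: StructureModel, reference: StructureModel,
                 min_coverage: float = 0.30) -> list:
    """Pair residues of two cleaned structures by global sequence alignment.

    Returns ``[(ResidueKey_model, ResidueKey_reference), ...]``.  A pair is
    emitted only when both alignment columns are occupied and the residue
    names match, so point mutations and unresolved residues drop out rather
    than contaminating RMSD sums.
    """
    keys_m = list(model.residues)
    keys_r = list(reference.residues)
    if not keys_m or not keys_r:
        raise MappingError("cannot map residues of an empty structure")
    seq_m = model.one_letter_sequence()
    seq_r = reference.one_letter_sequence()
    alignment = _aligner().align(seq_m, seq_r)[0]
    pairs = []
    blocks_m, blocks_r = alignment.aligned
    for (ms, me), (rs, re_) in zip(blocks_m, blocks_r):
        for i, j in zip(range(ms, me), range(rs, re_)):
            if keys_m[i].residue_name == keys_r[j].residue_name:
                pairs.append((keys_m[i], keys_r[j]))
    shorter = min(len(keys_m), len(keys_r))
    if len(pairs) < min_coverage * shorter:
        raise MappingError(
            f"alignment covers {len(pairs)}/{shorter} residues "
            f"(< {min_coverage:.0%} of the shorter sequence)"
        )
    return pairs


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _pdb_atom_line(serial: int, rec: AtomRecord, key: ResidueKey, het: bool) -> str:
    name = rec.atom_name
    # PDB rule: names shorter than 4 chars start in column 14
    field = name.ljust(4) if len(name) == 4 else f" {name}".ljust(4)
    record = "HETATM" if het else "ATOM  "
    x, y, z = rec.coords
    return (
        f"{record}{serial:5d} {field}{rec.altloc or ' ':1s}{key.residue_name:>3s} "
        f"{key.chain_id:1s}{key.residue_number:4d}{key.insertion_code or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{rec.occupancy:6.2f}{0.0:6.2f}          "
        f"{rec.element:>2s}"
    )


def write_pdb(s: StructureModel, path) -> None:
    """Write a structure (and its ligands) back to PDB for inspection."""
    lines = []
    serial = 0
    last_chain = None
    for key, recs in s.residues.items():
        last_chain = key.chain_id
        for rec in recs:
            serial += 1
            lines.append(_pdb_atom_line(serial, rec, key, het=False))
    if last_chain is not None:
        serial += 1
        lines.append(f"TER   {serial:5d}")
    for key, recs in s.hetero.items():
        for rec in recs:
            serial += 1
            lines.append(_pdb_atom_line(serial, rec, key, het=True))
    for lig_id, pose in s.ligands.items():
        key = ResidueKey(chain_id=last_chain or "A", residue_number=900,
                         residue_name=lig_id[:3].upper() or "LIG")
        for name, el, xyz in zip(pose.atom_names, pose.elements, pose.coords):
            serial += 1
            rec = AtomRecord(atom_name=name, element=el, coords=xyz)
            lines.append(_pdb_atom_line(serial, rec, key, het=True))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
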