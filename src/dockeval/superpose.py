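"""Rigid-body superposition and the RMSD metrics used in docking evaluation.

All metrics follow the same recipe: choose an atom set, superpose with the
closed-form SVD Kabsch solution (reflections forbidden), and report the RMSD
over a stated atom set.

* ``full_structure_rmsd`` — all mapped heavy atoms, aligned and scored on the
  same set.
* ``pocket_rmsd`` — heavy (or backbone-only) atoms of the residues within a
  cutoff (default 5 A) of the reference-bound ligand, aligned and scored on
  the same set.
* ``pose_rmsd`` — the protein frames are aligned on residues within 15 A of
  the reference ligand; the resulting transform is applied to the predicted
  ligand pose and the ligand RMSD is computed with **no further fitting**,
  optionally minimized over graph automorphisms of the ligand.
* ``per_residue_divergence`` — after one global pocket alignment per
  candidate, the heavy-atom RMSD of each pocket residue, reduced by max
  across candidates and ranked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.spatial.distance import cdist

from .errors import CorrespondenceError, InsufficientOverlapError, SuperpositionError
from .structures import BACKBONE_ATOMS, LigandPose, ResidueKey, StructureModel, map_residues

__all__ = [
    "PocketDefinition",
    "Superposition",
    "ResidueDivergence",
    "kabsch_superpose",
    "define_pocket",
    "pocket_rmsd",
    "full_structure_rmsd",
    "pose_rmsd",
    "per_residue_divergence",
]

#: Number of graph automorphisms beyond which symmetry minimization falls
#: back to the identity correspondence.
AUTOMORPHISM_CAP = 10_000


@dataclass(frozen=True)
class PocketDefinition:
    """Residues with any heavy atom within ``cutoff`` of the reference ligand.

    Frozen against a named reference structure; membership is exactly the set
    satisfying the distance predicate, never hand-edited.
    """

    reference_structure_id: str
    ligand_id: str
    cutoff: float
    residues: frozenset

    def __contains__(self, key: ResidueKey) -> bool:
        return key in self.residues

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Superposition:
    """A proper rigid transform ``x -> R x + t`` with its fit RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-8
        ):
            raise SuperpositionError("rotation must be orthogonal with determinant +1")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-RMSD proper rotation + translation mapping ``mobile`` onto ``reference``.

    Standard SVD solution with reflection correction; rows of the two arrays
    must correspond one-to-one.  Collinear (rank-deficient) point sets are
    solvable but ill-conditioned, so they draw a warning.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise SuperpositionError("mobile and reference must be matching (N, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise SuperpositionError(f"superposition underdetermined: {n} < 3 atom pairs")
    cm, cr = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cm, Q - cr
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    if S[0] > 0 and S[1] / S[0] < 1e-8:
        warnings.warn("collinear atom set: superposition is ill-conditioned", stacklevel=2)
    d = np.sign(np.linalg.det(Vt.T @ U.T)) or 1.0
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cr - R @ cm
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


# ---------------------------------------------------------------------------
# Pocket definition
# ---------------------------------------------------------------------------

def _residues_within(structure: StructureModel, points: np.ndarray, cutoff: float) -> frozenset:
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    members = []
    for key in structure.residues:
        d = cdist(structure.residue_coords(key), points)
        if d.min() <= cutoff:
            members.append(key)
    return frozenset(members)


def define_pocket(reference: StructureModel, ligand_id: str, cutoff: float = 5.0) -> PocketDefinition:
    """Binding pocket: residues with any heavy atom within ``cutoff`` of the ligand."""
    if ligand_id not in reference.ligands:
        raise CorrespondenceError(f"{reference.structure_id}: no ligand {ligand_id!r}; clean first")
    pose = reference.ligands[ligand_id]
    if pose.n_atoms == 0:
        raise CorrespondenceError(f"ligand {ligand_id!r} has no heavy atoms")
    return PocketDefinition(
        reference_structure_id=reference.structure_id,
        ligand_id=ligand_id,
        cutoff=float(cutoff),
        residues=_residues_within(reference, pose.coords, cutoff),
    )


# ---------------------------------------------------------------------------
# Atom pairing helpers
# ---------------------------------------------------------------------------

def _paired_coords(
    model: StructureModel,
    reference: StructureModel,
    pairs: list,
    residue_filter: Optional[Callable[[ResidueKey], bool]] = None,
    atom_filter: Optional[Callable[[str], bool]] = None,
):
    """Coordinates of atoms shared (by atom_name) between mapped residues."""
    A, B = [], []
    for km, kr in pairs:
        if residue_filter is not None and not residue_filter(kr):
            continue
        recs_m = {r.atom_name: r for r in model.residues[km]}
        for rec in reference.residues[kr]:
            name = rec.atom_name
            if name in recs_m and (atom_filter is None or atom_filter(name)):
                A.append(recs_m[name].coords)
                B.append(rec.coords)
    A = np.array(A, dtype=float).reshape(-1, 3)
    B = np.array(B, dtype=float).reshape(-1, 3)
    return A, B


def _iterative_kabsch(A: np.ndarray, B: np.ndarray, cycles: int) -> Superposition:
    """Optional outlier-rejection alignment: drop atoms > 2x current RMSD, <= ``cycles`` rounds."""
    sup = kabsch_superpose(A, B)
    for _ in range(cycles):
        dev = np.linalg.norm(sup.apply(A) - B, axis=1)
        keep = dev <= 2.0 * max(sup.rmsd, 1e-12)
        if keep.all() or keep.sum() < 3:
            break
        A, B = A[keep], B[keep]
        sup = kabsch_superpose(A, B)
    return sup


def _aligned_rmsd(A: np.ndarray, B: np.ndarray, cycles: int = 0) -> Superposition:
    if len(A) < 3:
        raise InsufficientOverlapError(f"only {len(A)} shared atoms (< 3)")
    if cycles > 0:
        sup = _iterative_kabsch(A, B, min(cycles, 5))
        # RMSD is still reported over the full stated atom set
        dev = np.linalg.norm(sup.apply(A) - B, axis=1)
        return Superposition(sup.rotation, sup.translation,
                             float(np.sqrt(np.mean(dev**2))), len(A))
    return kabsch_superpose(A, B)


# ---------------------------------------------------------------------------
# RMSD metrics
# ---------------------------------------------------------------------------

def pocket_rmsd(
    model: StructureModel,
    reference: StructureModel,
    pocket: PocketDefinition,
    scope: str = "all_heavy",
    cycles: int = 0,
    pairs: Optional[list] = None,
) -> float:
    """Binding-pocket RMSD: align and score on the same pocket atom set.

    ``scope`` is ``"all_heavy"`` or ``"backbone"`` (N, CA, C, O only).
    ``cycles`` > 0 enables iterative outlier rejection during alignment (the
    RMSD is still reported over the full pocket atom set).
    """
    if scope not in ("all_heavy", "backbone"):
        raise ValueError(f"scope must be 'all_heavy' or 'backbone', got {scope!r}")
    atom_filter = (lambda name: name in BACKBONE_ATOMS) if scope == "backbone" else None
    if pairs is None:
        pairs = map_residues(model, reference)
    A, B = _paired_coords(model, reference, pairs,
                          residue_filter=lambda kr: kr in pocket,
                          atom_filter=atom_filter)
    return _aligned_rmsd(A, B, cycles).rmsd


def full_structure_rmsd(
    model: StructureModel,
    reference: StructureModel,
    cycles: int = 0,
    pairs: Optional[list] = None,
) -> float:
    """All-heavy-atom RMSD over every mapped residue."""
    if pairs is None:
        pairs = map_residues(model, reference)
    A, B = _paired_coords(model, reference, pairs)
    return _aligned_rmsd(A, B, cycles).rmsd


def pose_rmsd(
    predicted: LigandPose,
    model: StructureModel,
    reference: StructureModel,
    reference_pose: LigandPose,
    symmetry: bool = True,
    shell: float = 15.0,
    cycles: int = 0,
    pairs: Optional[list] = None,
) -> float:
    """Ligand-pose RMSD after aligning the protein frames on the 15 A shell.

    The model is superposed onto the reference using heavy atoms of mapped
    residues within ``shell`` of the reference ligand; that transform is
    applied to the predicted pose and the ligand heavy-atom RMSD is computed
    without further fitting.  With ``symmetry`` the RMSD is minimized over
    graph automorphisms of the ligand (capped; falls back to identity).
    """
    if predicted.n_atoms != reference_pose.n_atoms:
        raise CorrespondenceError(
            f"pose atom counts differ: {predicted.n_atoms} vs {reference_pose.n_atoms}"
        )
    shell_residues = _residues_within(reference, reference_pose.coords, shell)
    if pairs is None:
        pairs = map_residues(model, reference)
    A, B = _paired_coords(model, reference, pairs,
                          residue_filter=lambda kr: kr in shell_residues)
    sup = _aligned_rmsd(A, B, cycles)
    pred = sup.apply(predicted.coords)
    ref = reference_pose.coords
    perms = [np.arange(reference_pose.n_atoms)]
    graph = reference_pose.graph or predicted.graph
    if symmetry and graph is not None:
        from .ligands import automorphisms

        perms = automorphisms(graph, cap=AUTOMORPHISM_CAP)
    best = np.inf
    for perm in perms:
        r = np.sqrt(np.mean(np.sum((pred[perm] - ref) ** 2, axis=1)))
        best = min(best, float(r))
    return best


@dataclass
class ResidueDivergence:
    """Max per-residue heavy-atom RMSD of one pocket residue across candidates."""

    residue: ResidueKey
    max_rmsd: float
    per_candidate: dict = field(default_factory=dict)
    missing_in: list = field(default_factory=list)


def per_residue_divergence(
    candidates: list,
    reference: StructureModel,
    pocket: PocketDefinition,
) -> list:
    """Rank pocket residues by their maximum divergence across candidates.

    Each candidate is first aligned to the reference with one global pocket
    (all-heavy) superposition; per-residue RMSDs are then computed with no
    per-residue re-fitting.  Residues missing from a candidate are skipped
    for that candidate and listed in ``missing_in``.
    """
    if not candidates:
        raise ValueError("need at least one candidate structure")
    table: dict = {kr: ResidueDivergence(kr, 0.0) for kr in reference.residues if kr in pocket}
    for cand in candidates:
        pairs = map_residues(cand, reference)
        A, B = _paired_coords(cand, reference, pairs, residue_filter=lambda kr: kr in pocket)
        sup = _aligned_rmsd(A, B)
        mapped = {kr: km for km, kr in pairs}
        for kr, entry in table.items():
            if kr not in mapped:
                entry.missing_in.append(cand.structure_id)
                continue
            a, b = _paired_coords(cand, reference, [(mapped[kr], kr)])
            if len(a) == 0:
                entry.missing_in.append(cand.structure_id)
                continue
            r = float(np.sqrt(np.mean(np.sum((sup.apply(a) - b) ** 2, axis=1))))
            entry.per_candidate[cand.structure_id] = r
            entry.max_rmsd = max(entry.max_rmsd, r)
    ranked = sorted(table.values(), key=lambda e: -e.max_rmsd)
    return ranked
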