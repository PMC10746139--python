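"""Synthetic receptors, perturbed models, and simulated docking outcomes.

Desk-scale stand-ins for a cross-docking benchmark: a pseudo-receptor whose
backbone coils around a central cavity holding a rigid multi-atom ligand,
perturbed copies with controllable binding-pocket error, and predicted poses
whose correctness probability follows a logistic link of pocket RMSD,

    P(correct | pocket RMSD r) = expit(a + b r),   b <= 0,

so that every pipeline stage (superposition, pose classification,
pair-weighted statistics, kernel smoothing) can be exercised end-to-end with
a known ground truth.  The geometry is *not* physically realistic protein
structure; it is built to satisfy the properties the metrics rely on:
a non-empty 5 A pocket, no atom clashes below 1 A, a valid writable PDB,
and i.i.d. Gaussian model error split by backbone/side-chain atom class.

All randomness flows from one root seed through named substreams (receptor,
perturbation, pose, bernoulli), so single stages are independently
reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rng import substream
from .errors import GenerationError
from .ligands import AROMATIC, MolGraph, similarity_ratio
from .structures import AtomRecord, LigandPose, ResidueKey, StructureModel
from .superpose import define_pocket, kabsch_superpose, map_residues, pocket_rmsd, pose_rmsd

__all__ = [
    "PoseErrorScales",
    "StudyConfig",
    "SyntheticComplex",
    "StudyResult",
    "generate_receptor",
    "perturb_model",
    "generate_pose",
    "generate_study",
]

_AA3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

# Solenoid geometry constants (Angstrom / radians)
_RADIUS = 9.0
_RES_PER_TURN = 15
_RISE = 4.8 / _RES_PER_TURN


@dataclass(frozen=True)
class PoseErrorScales:
    """Scales of simulated pose error (Angstrom).

    ``sigma_correct`` jitters correct poses; incorrect poses get a rigid
    displacement of length ``displacement_incorrect`` plus rotation and
    jitter ``sigma_incorrect``.
    """

    sigma_correct: float = 0.35
    sigma_incorrect: float = 0.8
    displacement_incorrect: float = 4.0

    def __post_init__(self) -> None:
        if min(self.sigma_correct, self.sigma_incorrect, self.displacement_incorrect) <= 0:
            raise ValueError("all pose-error scales must be positive")


@dataclass
class StudyConfig:
    """Parameters of a simulated cross-docking study.

    ``pocket_rmsd_distribution`` maps receptor kind to the (shape, scale) of
    a Gamma distribution of target pocket RMSDs; defaults give mean pocket
    errors of about 0.9 A for re-determined experimental structures, 1.3 A
    for the deep-learning kind and 3.3 A for the template-based kind, i.e.
    the qualitative ordering such benchmarks report.  ``link`` is the
    ``(a, b)`` of the logistic success model, shared by all kinds unless
    overridden per kind via ``link_by_kind``.
    """

    n_proteins: int = 6
    ligands_per_protein: int = 3
    receptors_per_pair: dict = field(
        default_factory=lambda: {"experimental": 2, "af2": 1, "traditional": 2}
    )
    pocket_rmsd_distribution: dict = field(
        default_factory=lambda: {
            "experimental": (2.0, 0.45),
            "af2": (2.6, 0.5),
            "traditional": (3.3, 1.0),
        }
    )
    link: tuple = (4.0, -4.0)
    link_by_kind: Optional[dict] = None
    pose_error_scales: PoseErrorScales = field(default_factory=PoseErrorScales)
    n_residues: int = 24
    include_self_dock: bool = True
    drop_terminal_frac: float = 0.0
    keep_structures: bool = False
    seed: int = 0
    allow_increasing: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.pose_error_scales, PoseErrorScales):
            self.pose_error_scales = PoseErrorScales(*self.pose_error_scales)
        for kind, (shape, scale) in self.pocket_rmsd_distribution.items():
            if shape <= 0 or scale <= 0:
                raise ValueError(f"Gamma parameters for {kind!r} must be positive")
        for a, b in self._all_links():
            if b > 0 and not self.allow_increasing:
                raise ValueError(
                    "success must be non-increasing in pocket RMSD (b <= 0); "
                    "set allow_increasing=True to override"
                )

    def _all_links(self):
        links = [self.link]
        if self.link_by_kind:
            links += [v for v in self.link_by_kind.values() if not callable(v)]
        return links

    def link_for(self, kind: str) -> Callable[[float], float]:
        """Success probability as a function of pocket RMSD for one kind.

        Per-kind overrides may be ``(a, b)`` logistic parameters or an
        arbitrary callable ``r -> p`` (clipped to [0, 1]).
        """
        entry = (self.link_by_kind or {}).get(kind, self.link)
        if callable(entry):
            return lambda r: float(np.clip(entry(r), 0.0, 1.0))
        a, b = entry
        return lambda r: float(expit(a + b * r))


@dataclass
class SyntheticComplex:
    """A reference complex plus (optionally retained) models and poses."""

    reference: StructureModel
    models: list = field(default_factory=list)
    poses: list = field(default_factory=list)


@dataclass
class StudyResult:
    """Output of :func:`generate_study`.

    ``manifest`` holds one row per docking record with both the measured
    quantities (pocket_rmsd, pose_rmsd — computed by the real superposition
    pipeline) and the generator's truth columns (``true_*``).
    """

    manifest: pd.DataFrame
    complexes: dict
    config: StudyConfig
    n_skipped: int = 0

    @property
    def truth(self) -> pd.DataFrame:
        cols = [c for c in self.manifest.columns if c.startswith("true_")]
        return self.manifest[["protein_id", "ligand_id", "receptor_id"] + cols]


# ---------------------------------------------------------------------------
# Receptor and ligand construction
# ---------------------------------------------------------------------------

def _ligand_geometry(variant_rng: np.random.Generator):
    """Ring (5 or 6 aromatic carbons) plus a short heteroatom chain.

    Returns (atom_names, elements, coords, MolGraph).  8-14 heavy atoms.
    """
    ring_n = int(variant_rng.choice([5, 6]))
    chain_m = int(variant_rng.integers(3, 9))
    side = 1.4
    r_ring = side / (2.0 * math.sin(math.pi / ring_n))
    coords = []
    elements = []
    for i in range(ring_n):
        ang = 2.0 * math.pi * i / ring_n
        coords.append([r_ring * math.cos(ang), r_ring * math.sin(ang), 0.0])
        elements.append("C")
    hetero_pool = ["C", "C", "O", "C", "N", "C", "C", "C"]
    start = int(variant_rng.integers(0, len(hetero_pool)))
    for j in range(1, chain_m + 1):
        phi = 0.8 * j
        coords.append([2.0 * math.cos(phi), 2.0 * math.sin(phi), 1.1 + 0.75 * j])
        elements.append(hetero_pool[(start + j) % len(hetero_pool)])
    coords = np.array(coords, dtype=float)
    bonds = [(i, (i + 1) % ring_n, AROMATIC) for i in range(ring_n)]
    bonds.append((0, ring_n, 1.0))  # ring-to-chain attachment
    for j in range(chain_m - 1):
        bonds.append((ring_n + j, ring_n + j + 1, 1.0))
    graph = MolGraph(elements=tuple(elements), bonds=tuple(sorted(
        (min(i, j), max(i, j), o) for i, j, o in bonds)))
    counts: dict = {}
    names = []
    for el in elements:
        counts[el] = counts.get(el, 0) + 1
        names.append(f"{el}{counts[el]}")
    return names, elements, coords, graph


def make_ligand(variant_seed: int, ligand_id: str = "LIG") -> LigandPose:
    """A rigid multi-atom ligand pose centered in the receptor cavity."""
    rng = substream(variant_seed, "ligand")
    names, elements, coords, graph = _ligand_geometry(rng)
    return LigandPose(ligand_id, names, elements, coords, graph=graph)


def generate_receptor(
    n_residues: int,
    seed: int,
    ligand: Optional[LigandPose] = None,
    structure_id: Optional[str] = None,
) -> StructureModel:
    """Deterministic pseudo-receptor enclosing a central ligand-bearing cavity.

    Backbone atoms (N, CA, C, O) follow a coiled path of radius 9 A; each
    residue carries 2-4 side-chain pseudo-atoms pointing inward so that the
    5 A pocket of the central ligand is non-empty by construction.  Repeat
    calls with the same seed give byte-identical PDB output.
    """
    if n_residues < 12:
        raise GenerationError(f"need at least 12 residues to enclose a cavity, got {n_residues}")
    rng = substream(seed, "receptor")
    z0 = -(n_residues * _RISE) / 2.0
    residues: dict = {}
    for i in range(n_residues):
        theta = 2.0 * math.pi * i / _RES_PER_TURN
        ca = np.array([_RADIUS * math.cos(theta), _RADIUS * math.sin(theta), z0 + i * _RISE])
        # unit tangent of the helical path and outward radial direction
        t_vec = np.array([-_RADIUS * math.sin(theta), _RADIUS * math.cos(theta),
                          _RISE * _RES_PER_TURN / (2.0 * math.pi)])
        t_hat = t_vec / np.linalg.norm(t_vec)
        n_hat = np.array([math.cos(theta), math.sin(theta), 0.0])
        z_hat = np.array([0.0, 0.0, 1.0])
        name3 = _AA3[int(rng.integers(0, len(_AA3)))]
        key = ResidueKey(chain_id="A", residue_number=i + 1, residue_name=name3)
        recs = [
            AtomRecord("N", "N", ca - 1.2 * t_hat + 0.55 * z_hat),
            AtomRecord("CA", "C", ca),
            AtomRecord("C", "C", ca + 1.2 * t_hat + 0.55 * z_hat),
            AtomRecord("O", "O", ca + 1.2 * t_hat + 0.7 * n_hat + 1.45 * z_hat),
        ]
        n_side = int(rng.integers(2, 5))
        jitter = float(rng.uniform(-0.3, 0.3))
        cb = ca - 1.53 * n_hat
        recs.append(AtomRecord("CB", "C", cb))
        if n_side >= 2:
            cg = cb - 1.45 * n_hat + jitter * z_hat
            recs.append(AtomRecord("CG", "C", cg))
            if n_side >= 3:
                recs.append(AtomRecord("CD1", "C", cg - 1.4 * n_hat + 0.6 * z_hat))
            if n_side >= 4:
                recs.append(AtomRecord("CD2", "C", cg - 1.4 * n_hat - 0.6 * z_hat))
        residues[key] = recs
    if ligand is None:
        ligand = make_ligand(seed)
    model = StructureModel(
        structure_id=structure_id or f"synth{seed}",
        kind="synthetic",
        residues=residues,
        ligands={ligand.ligand_id: ligand.copy()},
    )
    return model


# ---------------------------------------------------------------------------
# Perturbation
# ---------------------------------------------------------------------------

def _flat_atoms(s: StructureModel):
    keys, names, coords, backbone = [], [], [], []
    for key, rec in s.atoms():
        keys.append(key)
        names.append(rec.atom_name)
        coords.append(rec.coords)
        backbone.append(rec.is_backbone)
    return keys, names, np.array(coords, dtype=float), np.array(backbone, dtype=bool)


def _with_coords(
    reference: StructureModel,
    coords: np.ndarray,
    structure_id: str,
    kind: str,
    drop_keys: Optional[set] = None,
) -> StructureModel:
    residues: dict = {}
    k = 0
    for key, recs in reference.residues.items():
        if drop_keys and key in drop_keys:
            k += len(recs)
            continue
        residues[key] = [
            AtomRecord(r.atom_name, r.element, coords[k + i], r.occupancy)
            for i, r in enumerate(recs)
        ]
        k += len(recs)
    return StructureModel(structure_id=structure_id, kind=kind, residues=residues)


def perturb_model(
    reference: StructureModel,
    sigma_backbone: float,
    sigma_sidechain: float,
    seed: int,
    drop_terminal_frac: float = 0.0,
    kind: str = "synthetic",
    structure_id: Optional[str] = None,
) -> StructureModel:
    """Gaussian-perturbed copy of a reference structure, ligand removed.

    Adds i.i.d. zero-mean noise per coordinate with a per-atom-class sigma
    (backbone N/CA/C/O vs side-chain pseudo-atoms), emulating model error.
    ``drop_terminal_frac`` removes a seeded random fraction (up to 10%) of
    terminal residues to exercise residue mapping.
    """
    if sigma_backbone < 0 or sigma_sidechain < 0:
        raise ValueError("sigmas must be non-negative")
    rng = substream(seed, "perturbation")
    _, _, coords, backbone = _flat_atoms(reference)
    sigma = np.where(backbone, sigma_backbone, sigma_sidechain)[:, None]
    new = coords + rng.standard_normal(coords.shape) * sigma
    drop_keys: set = set()
    if drop_terminal_frac > 0:
        frac = min(drop_terminal_frac, 0.10)
        keys = list(reference.residues)
        n_drop = int(rng.integers(0, max(1, round(frac * len(keys))) + 1))
        for d in range(n_drop):
            drop_keys.add(keys[d] if rng.random() < 0.5 else keys[-1 - d])
    return _with_coords(
        reference, new,
        structure_id or f"{reference.structure_id}-pert{seed}",
        kind if kind in ("experimental", "af2", "traditional", "synthetic") else "synthetic",
        drop_keys,
    )


# ---------------------------------------------------------------------------
# Pose generation
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator, min_angle: float, max_angle: float) -> np.ndarray:
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(min_angle, max_angle)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def generate_pose(
    reference_pose: LigandPose,
    correct: bool,
    scales: PoseErrorScales,
    seed: int,
    max_tries: int = 100,
) -> LigandPose:
    """A simulated predicted pose of guaranteed correctness class.

    Correct poses are the reference plus small jitter (resampled until the
    in-frame RMSD clears the 2.0 A criterion with margin); incorrect poses
    get a rigid displacement plus rotation (resampled until clearly beyond
    the criterion).  The margins keep the class stable under the small
    additional error introduced by protein-frame alignment downstream.
    """
    if not isinstance(scales, PoseErrorScales):
        scales = PoseErrorScales(*scales)
    rng = substream(seed, "pose")
    ref = reference_pose.coords
    centroid = ref.mean(axis=0)
    for _ in range(max_tries):
        if correct:
            cand = ref + rng.normal(0.0, scales.sigma_correct, ref.shape)
            rmsd = float(np.sqrt(np.mean(np.sum((cand - ref) ** 2, axis=1))))
            if rmsd <= 1.5:  # margin under the 2.0 A criterion
                break
        else:
            R = _random_rotation(rng, math.pi / 2, math.pi)
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            cand = (ref - centroid) @ R.T + centroid
            cand = cand + scales.displacement_incorrect * direction
            cand = cand + rng.normal(0.0, scales.sigma_incorrect, ref.shape)
            rmsd = float(np.sqrt(np.mean(np.sum((cand - ref) ** 2, axis=1))))
            if rmsd >= 3.0:  # margin above the 2.0 A criterion
                break
    else:
        raise GenerationError(
            f"could not realize a {'correct' if correct else 'incorrect'} pose "
            f"in {max_tries} tries"
        )
    out = reference_pose.copy()
    out.coords = cand
    return out


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

def _realize_pocket_target(
    ref_coords: np.ndarray,
    backbone: np.ndarray,
    pocket_mask: np.ndarray,
    target: float,
    rng: np.random.Generator,
    tol: float = 0.10,
    max_iter: int = 8,
):
    """Scale one noise realization so the pocket RMSD hits ``target`` within 10%.

    Side-chain atoms get twice the backbone sigma.  Returns (coords, sigma)
    or None when the target is unrealizable for this noise draw.
    """
    eps = rng.standard_normal(ref_coords.shape)
    class_scale = np.where(backbone, 1.0, 2.0)[:, None]
    template = eps * class_scale
    ref_pocket = ref_coords[pocket_mask]

    def achieved(s: float) -> float:
        moved = ref_pocket + s * template[pocket_mask]
        return kabsch_superpose(moved, ref_pocket).rmsd

    if target <= 1e-6:
        return ref_coords.copy(), 0.0
    s = target / math.sqrt(3.0)
    for _ in range(max_iter):
        r = achieved(s)
        if abs(r - target) <= tol * target:
            return ref_coords + s * template, s
        s *= target / max(r, 1e-12)
    return None


def generate_study(config: StudyConfig) -> StudyResult:
    """Simulate a full cross-docking study and measure it with the real pipeline.

    For every protein x ligand x receptor the generator draws a target pocket
    RMSD from the kind's Gamma, builds a perturbed model realizing it, draws
    pose correctness from the logistic link at the *achieved* pocket RMSD,
    emits a predicted pose of that class, and then measures pocket RMSD and
    pose RMSD with :func:`dockeval.superpose.pocket_rmsd` /
    :func:`dockeval.superpose.pose_rmsd` — so the manifest contains
    pipeline-measured quantities alongside the generator's truth.
    """
    cfg = config
    rows = []
    complexes: dict = {}
    n_skipped = 0
    seed_rng = substream(cfg.seed, "study-seeds")
    graph_cache: dict = {}
    sim_cache: dict = {}

    def _similarity(pa: int, la: int, lb: int) -> float:
        key = (pa, min(la, lb), max(la, lb))
        if key not in sim_cache:
            ga = graph_cache[(pa, la)]
            gb = graph_cache[(pa, lb)]
            sim_cache[key] = similarity_ratio(ga, gb).ratio
        return sim_cache[key]

    for p in range(cfg.n_proteins):
        protein_id = f"P{p:03d}"
        receptor_seed = int(seed_rng.integers(2**31))
        ligands = {
            l: make_ligand(int(substream(cfg.seed, "ligand-variant", p, l).integers(2**31)))
            for l in range(cfg.ligands_per_protein)
        }
        for l, lig in ligands.items():
            graph_cache[(p, l)] = lig.graph
        for l in range(cfg.ligands_per_protein):
            ligand_id = f"{protein_id}-L{l}"
            ligand = ligands[l]
            reference = generate_receptor(
                cfg.n_residues, receptor_seed, ligand=ligand,
                structure_id=f"{ligand_id}-ref",
            )
            reference.kind = "experimental"
            pocket = define_pocket(reference, "LIG", cutoff=5.0)
            ref_pose = reference.ligands["LIG"]
            _, _, ref_coords, backbone = _flat_atoms(reference)
            pocket_mask = np.array(
                [key in pocket.residues for key, _ in reference.atoms()], dtype=bool
            )
            cx = SyntheticComplex(reference=reference)
            complexes[(protein_id, ligand_id)] = cx

            record_specs = [
                (kind, j)
                for kind, count in cfg.receptors_per_pair.items()
                for j in range(count)
            ]
            if cfg.include_self_dock:
                record_specs.append(("experimental", "self"))

            for kind, j in record_specs:
                self_dock = j == "self"
                item_seed = int(seed_rng.integers(2**31))
                link = cfg.link_for(kind)
                if self_dock:
                    receptor_id = f"{ligand_id}-ref"
                    model = reference
                    pairs = [(k, k) for k in reference.residues]
                    target = 0.0
                    sigma = 0.0
                else:
                    receptor_id = f"{protein_id}-{kind}{j}"
                    shape, scale = cfg.pocket_rmsd_distribution[kind]
                    target = float(substream(item_seed, "gamma").gamma(shape, scale))
                    realized = _realize_pocket_target(
                        ref_coords, backbone, pocket_mask, target,
                        substream(item_seed, "perturbation"),
                    )
                    if realized is None:
                        warnings.warn(
                            f"{receptor_id}: pocket-RMSD target {target:.2f} A "
                            "unrealizable; item skipped", stacklevel=2,
                        )
                        n_skipped += 1
                        continue
                    coords, sigma = realized
                    drop_keys: set = set()
                    if cfg.drop_terminal_frac > 0:
                        drop_rng = substream(item_seed, "drop")
                        keys = list(reference.residues)
                        frac = min(cfg.drop_terminal_frac, 0.10)
                        n_drop = int(drop_rng.integers(0, max(1, round(frac * len(keys))) + 1))
                        for d in range(n_drop):
                            drop_keys.add(keys[d] if drop_rng.random() < 0.5 else keys[-1 - d])
                    model = _with_coords(
                        reference, coords, f"{receptor_id}-for-{ligand_id}",
                        kind if kind != "experimental" else "experimental",
                        drop_keys,
                    )
                    pairs = map_residues(model, reference)
                r_pocket = pocket_rmsd(model, reference, pocket, pairs=pairs)
                p_true = link(r_pocket)
                correct = bool(substream(item_seed, "bernoulli").random() < p_true)
                pose = generate_pose(ref_pose, correct, cfg.pose_error_scales, item_seed)
                r_pose = pose_rmsd(pose, model, reference, ref_pose,
                                   symmetry=True, pairs=pairs)
                if kind == "experimental" and not self_dock:
                    if cfg.ligands_per_protein > 1:
                        other = (l + 1 + (j if isinstance(j, int) else 0)) % cfg.ligands_per_protein
                        if other == l:
                            other = (l + 1) % cfg.ligands_per_protein
                        sim = _similarity(p, l, other)
                    else:
                        sim = np.nan
                elif self_dock:
                    sim = 1.0
                else:
                    sim = np.nan
                if cfg.keep_structures:
                    cx.models.append(model)
                    cx.poses.append((pose, "correct" if correct else "incorrect"))
                rows.append({
                    "protein_id": protein_id,
                    "ligand_id": ligand_id,
                    "receptor_id": receptor_id,
                    "receptor_kind": kind,
                    "is_self_dock": self_dock,
                    "receptor_ligand_similarity": sim,
                    "pocket_rmsd": r_pocket,
                    "pose_rmsd": r_pose,
                    "true_target_pocket_rmsd": target,
                    "true_sigma_backbone": sigma,
                    "true_p_correct": p_true,
                    "true_correct": correct,
                })
    manifest = pd.DataFrame(rows)
    return StudyResult(manifest=manifest, complexes=complexes, config=cfg,
                       n_skipped=n_skipped)
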