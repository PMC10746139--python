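"""Kabsch superposition and the RMSD metric family."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dockeval.errors import CorrespondenceError, InsufficientOverlapError, SuperpositionError
from dockeval.ligands import AROMATIC, MolGraph
from dockeval.structures import LigandPose
from dockeval.superpose import (
    define_pocket,
    full_structure_rmsd,
    kabsch_superpose,
    per_residue_divergence,
    pocket_rmsd,
    pose_rmsd,
)
from dockeval.synthetic import generate_receptor, perturb_model

from conftest import build_structure, random_rotation, transform_structure, translate_structure


def brute_force_min_rmsd(P, Q, coarse_step=0.35, zooms=2):
    """Independent oracle: minimum RMSD over a zoomed axis-angle rotation grid.

    Searches rotation-vector space (axis * angle, |v| <= pi) on a coarse
    cubic grid, then refines around the best cell.  Translation is optimal
    analytically (centroids).  No SVD anywhere.
    """
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)

    def grid_min(center, half_width, n=15):
        axes = [np.linspace(c - half_width, c + half_width, n) for c in center]
        vv = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        mats = Rotation.from_rotvec(vv).as_matrix()
        rot = np.einsum("rij,nj->rni", mats, P0)
        rmsd = np.sqrt(np.mean(np.sum((rot - Q0[None]) ** 2, axis=2), axis=1))
        k = int(np.argmin(rmsd))
        return vv[k], float(rmsd[k])

    n_coarse = int(np.ceil(2 * np.pi / coarse_step))
    best_v, best = grid_min(np.zeros(3), np.pi, n=n_coarse)
    width = 2 * np.pi / n_coarse
    for _ in range(zooms):
        best_v, best = grid_min(best_v, width, n=15)
        width = 2 * width / 14
    return best


class TestKabsch:
    def test_identical_points_identity(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-10)

    def test_rigid_motion_recovered_exactly(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((5, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ R.T + np.array([3.0, -1.0, 2.0])
        sup = kabsch_superpose(pts, moved)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(sup.apply(pts), moved, atol=1e-10)

    def test_matches_rotation_grid_oracle(self):
        """Closed-form solution equals the brute-force axis-angle minimum."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(3, 6))
            P = rng.standard_normal((n, 3)) * 2
            Q = rng.standard_normal((n, 3)) * 2
            assert kabsch_superpose(P, Q).rmsd == pytest.approx(
                brute_force_min_rmsd(P, Q), abs=1e-3)

    def test_underdetermined_and_collinear(self):
        with pytest.raises(SuperpositionError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.warns(UserWarning, match="collinear"):
            sup = kabsch_superpose(line, line + 1.0)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_no_reflections(self):
        # mirror-image point sets must still yield det(R) = +1
        rng = np.random.default_rng(3)
        P = rng.standard_normal((6, 3))
        Q = P.copy()
        Q[:, 0] = -Q[:, 0]
        sup = kabsch_superpose(P, Q)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-10)
        assert sup.rmsd > 0.1


def _site(ligand_xyz=((0.0, 0.0, 0.0),)):
    """One-residue-per-shell toy site around a ligand at given coordinates."""
    lig = LigandPose("LIG", [f"C{i+1}" for i in range(len(ligand_xyz))],
                     ["C"] * len(ligand_xyz), np.array(ligand_xyz, float))
    res = [
        ("ALA", [("N", "N", (0, 0, 4.9)), ("CA", "C", (1.4, 0, 4.9)), ("C", "C", (2, 1, 5.5))]),
        ("GLY", [("N", "N", (0, 0, 5.1)), ("CA", "C", (0, 1.4, 5.4)), ("C", "C", (1, 2, 6))]),
        ("VAL", [("N", "N", (5.6, 0, 0)), ("CA", "C", (7.0, 0, 0)), ("C", "C", (7.6, 1.2, 0))]),
    ]
    return build_structure(res, ligands={"LIG": lig})


class TestDefinePocket:
    def test_threshold_inclusion_and_exclusion(self):
        s = _site()
        pocket = define_pocket(s, "LIG", cutoff=5.0)
        names = {k.residue_name for k in pocket.residues}
        assert "ALA" in names      # nearest atom at 4.9
        assert "GLY" not in names  # nearest atom at 5.1
        assert len(pocket) == 1

    def test_monotone_in_cutoff(self):
        s = generate_receptor(24, seed=2)
        inner = define_pocket(s, "LIG", cutoff=5.0)
        outer = define_pocket(s, "LIG", cutoff=6.0)
        assert inner.residues <= outer.residues


class TestPocketAndFullRmsd:
    @pytest.fixture
    def reference(self):
        return generate_receptor(24, seed=9)

    def test_rigid_transform_gives_zero(self, reference):
        rng = np.random.default_rng(1)
        moved = transform_structure(reference, random_rotation(rng), np.array([4.0, -2.0, 7.0]))
        pocket = define_pocket(reference, "LIG")
        assert pocket_rmsd(moved, reference, pocket) == pytest.approx(0.0, abs=1e-9)
        assert pocket_rmsd(moved, reference, pocket, scope="backbone") == pytest.approx(0.0, abs=1e-9)
        assert full_structure_rmsd(moved, reference) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_translation_absorbed(self, reference):
        moved = translate_structure(reference, np.array([1.0, 0.0, 0.0]))
        pocket = define_pocket(reference, "LIG")
        assert pocket_rmsd(moved, reference, pocket) == pytest.approx(0.0, abs=1e-9)

    def test_matches_independent_superpose_oracle(self, reference):
        """Gaussian-perturbed pocket RMSD equals scipy align_vectors re-derivation."""
        from dockeval.structures import map_residues
        from dockeval.superpose import _paired_coords

        model = perturb_model(reference, 0.5, 0.5, seed=4)
        pocket = define_pocket(reference, "LIG")
        value = pocket_rmsd(model, reference, pocket)
        pairs = map_residues(model, reference)
        A, B = _paired_coords(model, reference, pairs, residue_filter=lambda k: k in pocket)
        rot, _ = Rotation.align_vectors(B - B.mean(axis=0), A - A.mean(axis=0))
        oracle = np.sqrt(np.mean(np.sum(
            (rot.apply(A - A.mean(axis=0)) - (B - B.mean(axis=0))) ** 2, axis=1)))
        assert value == pytest.approx(oracle, abs=1e-6)

    def test_closed_form_displacement_no_rotation(self):
        # two structures differing by centered displacements -> sqrt(mean |d|^2)
        base = [("ALA", [("N", "N", (0, 0, 0)), ("CA", "C", (2, 0, 0)), ("C", "C", (0, 2, 0)),
                         ("O", "O", (0, 0, 2))])]
        a = build_structure(base)
        disp = np.array([[0.3, 0, 0], [-0.3, 0, 0], [0, 0.3, 0], [0, -0.3, 0]])
        moved = [("ALA", [(n, el, tuple(np.asarray(x) + d))
                          for (n, el, x), d in zip(base[0][1], disp)])]
        b = build_structure(moved)
        # displacements sum to zero and have no net torque about the centroid
        # axes they act along, so the optimal fit is the identity
        expected = np.sqrt(np.mean(np.sum(disp**2, axis=1)))
        assert full_structure_rmsd(b, a) <= expected + 1e-9

    def test_insufficient_overlap_raises(self):
        a = _site()
        pocket = define_pocket(a, "LIG")
        b = build_structure([("ALA", [("N", "N", (0, 0, 4.9)), ("CA", "C", (1.4, 0, 4.9))])])
        with pytest.raises(InsufficientOverlapError):
            pocket_rmsd(b, a, pocket)

    def test_gaussian_concentration(self):
        """RMSD of sigma=0.5 noise on a large pocket concentrates below sqrt(3)*sigma."""
        reference = generate_receptor(80, seed=12)
        pocket = define_pocket(reference, "LIG", cutoff=12.0)
        n_atoms = sum(len(reference.residues[k]) for k in pocket.residues)
        assert n_atoms >= 200
        sigma = 0.5
        model = perturb_model(reference, sigma, sigma, seed=77)
        value = pocket_rmsd(model, reference, pocket)
        assert value <= np.sqrt(3) * sigma * 1.05
        assert value >= 0.5 * np.sqrt(3) * sigma


def _hexagon_pose(rotate_deg=0.0):
    ang = np.deg2rad(rotate_deg)
    theta = np.arange(6) * np.pi / 3 + ang
    coords = np.stack([1.4 * np.cos(theta), 1.4 * np.sin(theta), np.zeros(6)], axis=1)
    graph = MolGraph(elements=("C",) * 6,
                     bonds=tuple((i, (i + 1) % 6, AROMATIC) for i in range(5))
                     + ((0, 5, AROMATIC),))
    return LigandPose("BNZ", [f"C{i+1}" for i in range(6)], ["C"] * 6, coords, graph=graph)


class TestPoseRmsd:
    @pytest.fixture
    def frame(self):
        ref = generate_receptor(24, seed=21)
        return ref, ref.ligands["LIG"]

    def test_identical_everything_zero(self, frame):
        ref, pose = frame
        assert pose_rmsd(pose, ref, ref, pose) == pytest.approx(0.0, abs=1e-9)

    def test_joint_rigid_motion_zero(self, frame):
        ref, pose = frame
        rng = np.random.default_rng(5)
        R, t = random_rotation(rng), np.array([10.0, 5.0, -3.0])
        moved = transform_structure(ref, R, t)
        assert pose_rmsd(moved.ligands["LIG"], moved, ref, pose) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_ligand_translation_exact(self, frame):
        ref, pose = frame
        shifted = pose.transformed(np.eye(3), np.array([0.6, 0.8, 0.0]))  # length 1.0
        assert pose_rmsd(shifted, ref, ref, pose) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry_flag_on_benzene_rotation(self):
        """A 60-degree in-place ring rotation is an automorphism: RMSD 0 with
        symmetry, positive without."""
        ref = generate_receptor(24, seed=3, ligand=_hexagon_pose())
        pose0 = ref.ligands["BNZ"]
        rotated = _hexagon_pose(rotate_deg=60.0)
        assert pose_rmsd(rotated, ref, ref, pose0, symmetry=True) == pytest.approx(0.0, abs=1e-9)
        assert pose_rmsd(rotated, ref, ref, pose0, symmetry=False) > 1.0

    def test_atom_count_mismatch_raises(self, frame):
        ref, pose = frame
        short = LigandPose("LIG", pose.atom_names[:-1], pose.elements[:-1], pose.coords[:-1])
        with pytest.raises(CorrespondenceError):
            pose_rmsd(short, ref, ref, pose)


class TestPerResidueDivergence:
    def test_identical_candidates_all_zero(self):
        ref = generate_receptor(24, seed=30)
        pocket = define_pocket(ref, "LIG")
        out = per_residue_divergence([ref, ref], ref, pocket)
        assert len(out) == len(pocket)
        assert all(e.max_rmsd == pytest.approx(0.0, abs=1e-9) for e in out)

    def test_displaced_side_chain_ranks_first(self):
        ref = generate_receptor(24, seed=30)
        pocket = define_pocket(ref, "LIG")
        cand = transform_structure(ref, np.eye(3), np.zeros(3))
        target = sorted(pocket.residues, key=lambda k: k.residue_number)[0]
        for rec in cand.residues[target]:
            if not rec.is_backbone:
                rec.coords = rec.coords + np.array([0.0, 0.0, 2.0])
        out = per_residue_divergence([cand], ref, pocket)
        assert out[0].residue.same_position(target)
        assert out[0].max_rmsd > 0.5

    def test_disjoint_perturbations_union_with_own_max(self):
        ref = generate_receptor(24, seed=30)
        pocket = define_pocket(ref, "LIG")
        keys = sorted(pocket.residues, key=lambda k: k.residue_number)
        c1 = transform_structure(ref, np.eye(3), np.zeros(3))
        c2 = transform_structure(ref, np.eye(3), np.zeros(3))
        c1.structure_id, c2.structure_id = "cand1", "cand2"
        for rec in c1.residues[keys[0]]:
            if not rec.is_backbone:
                rec.coords = rec.coords + np.array([0, 0, 3.0])
        for rec in c2.residues[keys[1]]:
            if not rec.is_backbone:
                rec.coords = rec.coords + np.array([0, 0, 1.5])
        out = per_residue_divergence([c1, c2], ref, pocket)
        top_two = {out[0].residue.residue_number, out[1].residue.residue_number}
        assert top_two == {keys[0].residue_number, keys[1].residue_number}
        assert out[0].max_rmsd > out[1].max_rmsd
        # each residue's max comes from its own perturbed candidate
        assert out[0].per_candidate[c1.structure_id] > out[0].per_candidate[c2.structure_id]
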