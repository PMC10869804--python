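"""Superposition, ensemble precision, secondary structure, helix geometry."""

import math

import numpy as np
import pytest

from protodimer import (
    assign_secondary_structure,
    compare_structures,
    ensemble_rmsd,
    helix_axis,
    interhelix_angle,
    kabsch_superpose,
)
from protodimer.geometry import HelixAxis, helix_axis_for_segment
from protodimer.structure import Selection, Structure
from protodimer._peptide_build import HELIX_PHI_PSI, build_chain
from protodimer.synthetic import GeneratorSpec, make_toy_dimer, perturb_ensemble
from tests.conftest import random_rotation


class TestKabsch:
    def test_identical_sets_give_zero_rmsd_and_identity(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_rigid_motion_recovered_exactly(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        rot = random_rotation(rng)
        moved = pts @ rot.T + np.array([5.0, -3.0, 2.0])
        res = kabsch_superpose(pts, moved)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_beats_thousand_random_rotations(self):
        """The closed-form optimum is at least as good as any sampled rotation."""
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(10, 3))
        mov = ref + rng.normal(scale=0.3, size=ref.shape)
        opt = kabsch_superpose(ref, mov).rmsd
        ref_c = ref - ref.mean(axis=0)
        mov_c = mov - mov.mean(axis=0)
        for _ in range(1000):
            rot = random_rotation(rng)
            rmsd = math.sqrt(np.mean(np.sum((mov_c @ rot.T - ref_c) ** 2, axis=1)))
            assert opt <= rmsd + 1e-12

    def test_matches_scipy_reference(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        ref = rng.normal(size=(15, 3))
        mov = ref + rng.normal(scale=0.5, size=ref.shape)
        ours = kabsch_superpose(ref, mov)
        rot, rssd = Rotation.align_vectors(
            ref - ref.mean(axis=0), mov - mov.mean(axis=0)
        )
        assert ours.rmsd == pytest.approx(rssd / math.sqrt(len(ref)), rel=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]) * 0.0
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)


class TestEnsembleRMSD:
    def test_identical_models_give_zero(self, toy_dimer):
        st, _ = toy_dimer
        ens = perturb_ensemble(st, 0.0, 0.0, n_models=5, seed=0)
        mean_rmsd, per_model = ensemble_rmsd(ens)
        assert mean_rmsd == pytest.approx(0.0, abs=1e-10)
        assert len(per_model) == 5

    def test_gaussian_scatter_matches_closed_form(self, toy_dimer):
        """Isotropic noise sigma gives mean RMSD-to-mean ~ sigma sqrt(3 (m-1)/m)."""
        st, _ = toy_dimer
        sigma, m = 0.5, 20
        ens = perturb_ensemble(st, sigma, sigma, n_models=m, seed=11)
        mean_rmsd, _ = ensemble_rmsd(ens, atom_class="heavy")
        expected = sigma * math.sqrt(3.0) * math.sqrt((m - 1) / m)
        assert mean_rmsd == pytest.approx(expected, rel=0.05)

    def test_invariant_to_prerotating_one_model(self, toy_dimer):
        st, _ = toy_dimer
        ens = perturb_ensemble(st, 0.3, 0.5, n_models=6, seed=4)
        base, _ = ensemble_rmsd(ens, atom_class="backbone")
        rng = np.random.default_rng(5)
        rot = random_rotation(rng)
        shift = np.array([10.0, -4.0, 7.0])
        for chain in ens.models[2]:
            for res in chain.residues:
                for atom in res.atoms:
                    atom.coord = rot @ atom.coord + shift
        moved, _ = ensemble_rmsd(ens, atom_class="backbone")
        assert moved == pytest.approx(base, abs=1e-6)

    def test_sidechain_noise_raises_heavy_rmsd_above_backbone(self, toy_dimer):
        st, _ = toy_dimer
        ens = perturb_ensemble(st, 0.3, 0.9, n_models=12, seed=6)
        bb, _ = ensemble_rmsd(ens, atom_class="backbone")
        heavy, _ = ensemble_rmsd(ens, atom_class="heavy")
        assert heavy > bb

    def test_single_model_rejected(self, toy_dimer):
        st, _ = toy_dimer
        with pytest.raises(ValueError):
            ensemble_rmsd(st)


class TestSecondaryStructure:
    def test_ideal_polyala_helix_is_one_segment(self):
        chain = build_chain("A", [HELIX_PHI_PSI] * 12)
        st = Structure(models=[[chain]], id="helix")
        ss = assign_secondary_structure(st)
        helices = ss.of_kind("helix")
        assert len(helices) == 1
        # termini lack phi or psi and stay coil
        assert helices[0][2] == 2 and helices[0][3] == 11

    def test_toy_dimer_segments_recovered_exactly(self, toy_dimer):
        st, truth = toy_dimer
        ss = assign_secondary_structure(st)
        for chain_id in ("A", "B"):
            segs = sorted(
                [(k, a, b) for k, c, a, b in ss.segments if c == chain_id],
                key=lambda s: s[1],
            )
            assert segs == [tuple(s) for s in truth["segments"]]

    def test_strands_require_hbond_support(self, separated_dimer):
        """Pulling the dimer apart removes the sheet: strands become coil."""
        st, _ = separated_dimer
        ss = assign_secondary_structure(st)
        assert ss.of_kind("strand") == []
        assert len(ss.of_kind("helix")) == 4  # helices survive


class TestHelixGeometry:
    def test_axis_of_ideal_z_helix_is_z(self):
        chain = build_chain("A", [HELIX_PHI_PSI] * 12)
        ca = np.array([r.atom("CA").coord for r in chain.residues])
        # align the built helix to z via its own principal axis, then re-fit
        ax = helix_axis(ca)
        assert np.linalg.norm(ax.direction) == pytest.approx(1.0)
        rng = np.random.default_rng(8)
        rot = random_rotation(rng)
        ax2 = helix_axis(ca @ rot.T)
        # equivariance: rotating coordinates rotates the axis
        assert np.degrees(
            np.arccos(np.clip(abs(np.dot(rot @ ax.direction, ax2.direction)), -1, 1))
        ) < 1.0

    def test_axis_orientation_follows_chain_direction(self):
        chain = build_chain("A", [HELIX_PHI_PSI] * 12)
        ca = np.array([r.atom("CA").coord for r in chain.residues])
        ax_fwd = helix_axis(ca)
        ax_rev = helix_axis(ca[::-1])
        assert np.dot(ax_fwd.direction, ax_rev.direction) == pytest.approx(-1.0, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            helix_axis(np.zeros((4, 3)))

    @pytest.mark.parametrize(
        "d1,d2,expected",
        [((0, 0, 1), (0, 0, 1), 0.0), ((0, 0, 1), (0, 1, 0), 90.0), ((0, 0, 1), (0, 0, -1), 180.0)],
    )
    def test_interhelix_angle_basic(self, d1, d2, expected):
        a1 = HelixAxis(origin=np.zeros(3), direction=np.array(d1, float))
        a2 = HelixAxis(origin=np.zeros(3), direction=np.array(d2, float))
        assert interhelix_angle(a1, a2) == pytest.approx(expected, abs=1e-9)
        assert interhelix_angle(a2, a1) == pytest.approx(expected, abs=1e-9)

    def test_flipping_one_axis_maps_theta_to_supplement(self):
        rng = np.random.default_rng(9)
        d1 = rng.normal(size=3)
        d2 = rng.normal(size=3)
        a1 = HelixAxis(np.zeros(3), d1 / np.linalg.norm(d1))
        a2 = HelixAxis(np.zeros(3), d2 / np.linalg.norm(d2))
        a2_flip = HelixAxis(np.zeros(3), -a2.direction)
        assert interhelix_angle(a1, a2) + interhelix_angle(a1, a2_flip) == pytest.approx(180.0)

    def test_generator_axes_recovered(self, toy_dimer):
        st, truth = toy_dimer
        spec = truth["spec"]
        for label, (lo, hi) in (("helix1", spec["helix1"]), ("helix2", spec["helix2"])):
            ax = helix_axis_for_segment(st, 0, "A", lo, hi)
            true_dir = np.array(truth["helix_axes_chain_a"][label])
            angle = np.degrees(np.arccos(np.clip(np.dot(ax.direction, true_dir), -1, 1)))
            assert angle < 1.0


class TestCompareStructures:
    def test_self_comparison_is_zero(self, toy_dimer):
        st, _ = toy_dimer
        pairing = [(("A", r.seq_num), ("A", r.seq_num)) for r in st.chain("A").residues]
        assert compare_structures(st, st, pairing) == pytest.approx(0.0, abs=1e-12)

    def test_rigidly_moved_copy_is_zero(self, toy_dimer):
        import copy

        st, _ = toy_dimer
        moved = copy.deepcopy(st)
        rng = np.random.default_rng(10)
        rot = random_rotation(rng)
        for chain in moved.models[0]:
            for res in chain.residues:
                for atom in res.atoms:
                    atom.coord = rot @ atom.coord + np.array([3.0, 4.0, 5.0])
        pairing = [(("A", r.seq_num), ("A", r.seq_num)) for r in st.chain("A").residues]
        assert compare_structures(st, moved, pairing) == pytest.approx(0.0, abs=1e-9)

    def test_hinge_bend_matches_grid_search_oracle(self, toy_dimer):
        """Kabsch RMSD equals a dense rotational grid search on a hinge-bent copy."""
        import copy

        st, _ = toy_dimer
        bent = copy.deepcopy(st)
        # bend helix2 of chain A by 15 degrees about a hinge at its first CA
        spec = GeneratorSpec()
        lo, hi = spec.helix2
        chain = bent.chain("A")
        hinge = chain.residue(lo).atom("CA").coord.copy()
        theta = np.deg2rad(15.0)
        axis = np.array([0.0, 1.0, 0.0])
        k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        rot = np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)
        for res in chain.residues:
            if res.seq_num >= lo:
                for atom in res.atoms:
                    atom.coord = rot @ (atom.coord - hinge) + hinge

        pairing = [(("A", r.seq_num), ("A", r.seq_num)) for r in st.chain("A").residues]
        ours = compare_structures(st, bent, pairing)
        assert ours > 0.1  # the bend is a real deformation

        # oracle: numeric minimization over rotation vectors from many random
        # starts — independent of the closed-form SVD solution
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        ca_ref = np.array([st.chain("A").residue(r.seq_num).atom("CA").coord
                           for r in st.chain("A").residues])
        ca_mov = np.array([bent.chain("A").residue(r.seq_num).atom("CA").coord
                           for r in bent.chain("A").residues])
        a = ca_ref - ca_ref.mean(axis=0)
        b = ca_mov - ca_mov.mean(axis=0)

        def rmsd_of(rotvec):
            rot = Rotation.from_rotvec(rotvec).as_matrix()
            return math.sqrt(np.mean(np.sum((b @ rot.T - a) ** 2, axis=1)))

        rng = np.random.default_rng(12)
        starts = [random_rotation(rng) for _ in range(200)]
        best_start = min(starts, key=lambda r: rmsd_of(Rotation.from_matrix(r).as_rotvec()))
        refined = minimize(
            rmsd_of, Rotation.from_matrix(best_start).as_rotvec(),
            method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-12},
        )
        assert ours <= refined.fun + 1e-9
        assert ours == pytest.approx(refined.fun, rel=1e-4)

    def test_too_few_pairs_rejected(self, toy_dimer):
        st, _ = toy_dimer
        with pytest.raises(ValueError):
            compare_structures(st, st, [(("A", 3), ("A", 3))])
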