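"""Trajectory analysis: dihedrals, free-energy surfaces, superposition,
and combined-ensemble PCA."""

import math

import numpy as np
import pytest

from slimbind.constants import KB_KJ_PER_MOL_K
from slimbind.synth import (
    AngleDistribution,
    broad_leucine_like,
    build_backbone,
    gen_peptide_traj,
    narrow_proline_like,
)
from slimbind.traj import (
    DihedralSeries,
    PeptideTrajectory,
    compute_phi_psi,
    dihedral_angle,
    free_energy_surface,
    pca_combined,
    superpose,
)


def _traj_from_angles(phi, psi):
    frames = np.stack([build_backbone(p, s) for p, s in zip(phi, psi)])
    atoms = [(r, "GLY", an) for r in range(phi.shape[1]) for an in ("N", "CA", "C")]
    return PeptideTrajectory(coords=frames, atoms=atoms)


def _delta(mu):
    return AngleDistribution((mu,), (1e9,), (1.0,))


class TestDihedrals:
    def test_collinear_atoms_rejected(self):
        pts = [np.array([float(i), 0.0, 0.0]) for i in range(4)]
        with pytest.raises(ValueError, match="degenerate"):
            dihedral_angle(*pts)

    def test_constructed_internal_coordinates_invert(self):
        phi = np.array([[0.0, -60.0, -65.0, 0.0]])
        psi = np.array([[-45.0, -45.0, 150.0, 0.0]])
        traj = _traj_from_angles(phi, psi)
        d1 = compute_phi_psi(traj, 1)
        assert d1.phi[0] == pytest.approx(-60.0, abs=1e-6)
        assert d1.psi[0] == pytest.approx(-45.0, abs=1e-6)
        d2 = compute_phi_psi(traj, 2)
        assert d2.phi[0] == pytest.approx(-65.0, abs=1e-6)
        assert d2.psi[0] == pytest.approx(150.0, abs=1e-6)

    def test_all_trans_backbone_has_psi_180(self):
        phi = np.array([[180.0, 180.0, 180.0]])
        psi = np.array([[180.0, 180.0, 180.0]])
        traj = _traj_from_angles(phi, psi)
        d = compute_phi_psi(traj, 1)
        assert abs(d.psi[0]) == pytest.approx(180.0, abs=1e-6)

    def test_terminal_residues_rejected_by_name(self):
        traj, _ = gen_peptide_traj(n_frames=2, n_residues=4, seed=0)
        with pytest.raises(ValueError, match="phi"):
            compute_phi_psi(traj, 0)
        with pytest.raises(ValueError, match="psi"):
            compute_phi_psi(traj, 3)

    def test_rigid_motion_invariance(self):
        traj, _ = gen_peptide_traj(n_frames=3, seed=2)
        d0 = compute_phi_psi(traj, 3)
        rng = np.random.default_rng(0)
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        moved = PeptideTrajectory(
            coords=traj.coords @ Q.T + np.array([5.0, -3.0, 11.0]),
            atoms=traj.atoms,
        )
        d1 = compute_phi_psi(moved, 3)
        assert np.allclose(d0.phi, d1.phi, atol=1e-9)
        assert np.allclose(d0.psi, d1.psi, atol=1e-9)


class TestFreeEnergySurface:
    def test_single_occupied_bin(self):
        d = DihedralSeries(1, np.full(50, -65.0), np.full(50, 150.0))
        fes = free_energy_surface(d, n_bins=36)
        assert fes.occupied_bin_count == 1
        assert np.nanmin(fes.delta_g) == 0.0
        assert np.isnan(fes.delta_g[~fes.occupied]).all()

    def test_two_bin_free_energy_difference(self):
        # counts 73 vs 27 at 310.15 K differ by kT ln(73/27) ~ 2.56 kJ/mol
        phi = np.concatenate([np.full(73, -65.0), np.full(27, 55.0)])
        psi = np.concatenate([np.full(73, 150.0), np.full(27, 40.0)])
        fes = free_energy_surface(DihedralSeries(1, phi, psi), n_bins=36, temperature=310.15)
        occupied_vals = np.sort(fes.delta_g[fes.occupied])
        expect = KB_KJ_PER_MOL_K * 310.15 * math.log(73 / 27)
        assert occupied_vals[0] == 0.0
        assert occupied_vals[1] == pytest.approx(expect, rel=1e-9)
        assert expect == pytest.approx(2.56, abs=0.01)

    def test_uniform_sampling_is_flat_within_noise(self):
        rng = np.random.default_rng(3)
        n = 20000
        d = DihedralSeries(1, rng.uniform(-180, 180, n), rng.uniform(-180, 180, n))
        fes = free_energy_surface(d, n_bins=6)
        assert fes.occupied_bin_count == 36
        assert np.nanmax(fes.delta_g) < 0.5

    def test_invariant_under_frame_duplication(self):
        traj, truth = gen_peptide_traj(n_frames=200, seed=4)
        d = compute_phi_psi(traj, 3)
        doubled = DihedralSeries(3, np.tile(d.phi, 2), np.tile(d.psi, 2))
        f1 = free_energy_surface(d)
        f2 = free_energy_surface(doubled)
        assert np.array_equal(f1.occupied, f2.occupied)
        assert np.allclose(
            f1.delta_g[f1.occupied], f2.delta_g[f2.occupied], atol=1e-12
        )

    def test_narrow_vs_broad_occupied_area_ordering(self):
        """A proline-like centre occupies strictly fewer Ramachandran
        bins than a leucine-like centre."""
        centre = 3
        model_n = [narrow_proline_like()] * 8
        model_b = list(model_n)
        model_b[centre] = broad_leucine_like()
        tn, _ = gen_peptide_traj(400, model_n, seed=5)
        tb, _ = gen_peptide_traj(400, model_b, seed=5)
        fn = free_energy_surface(compute_phi_psi(tn, centre))
        fb = free_energy_surface(compute_phi_psi(tb, centre))
        assert fn.occupied_bin_count < fb.occupied_bin_count


class TestSuperpose:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        aligned, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(aligned, pts, atol=1e-12)

    def test_recovers_rigid_transform(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(12, 3))
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        moved = ref @ Q.T + np.array([4.0, 5.0, -6.0])
        _, rmsd = superpose(moved, ref)
        assert rmsd < 1e-9

    def test_matches_quaternion_oracle(self):
        def quaternion_rmsd(X, Y):
            # Horn's closed-form absolute orientation -- independent path
            xc = X - X.mean(0)
            yc = Y - Y.mean(0)
            Sxx = xc.T @ yc
            K = np.empty((4, 4))
            K[0, 0] = Sxx[0, 0] + Sxx[1, 1] + Sxx[2, 2]
            K[0, 1] = K[1, 0] = Sxx[1, 2] - Sxx[2, 1]
            K[0, 2] = K[2, 0] = Sxx[2, 0] - Sxx[0, 2]
            K[0, 3] = K[3, 0] = Sxx[0, 1] - Sxx[1, 0]
            K[1, 1] = Sxx[0, 0] - Sxx[1, 1] - Sxx[2, 2]
            K[1, 2] = K[2, 1] = Sxx[0, 1] + Sxx[1, 0]
            K[1, 3] = K[3, 1] = Sxx[0, 2] + Sxx[2, 0]
            K[2, 2] = -Sxx[0, 0] + Sxx[1, 1] - Sxx[2, 2]
            K[2, 3] = K[3, 2] = Sxx[1, 2] + Sxx[2, 1]
            K[3, 3] = -Sxx[0, 0] - Sxx[1, 1] + Sxx[2, 2]
            lam = np.linalg.eigvalsh(K)[-1]
            e2 = (xc**2).sum() + (yc**2).sum()
            return math.sqrt(max(e2 - 2 * lam, 0.0) / X.shape[0])

        rng = np.random.default_rng(2)
        for _ in range(20):
            X = rng.normal(size=(10, 3))
            Y = rng.normal(size=(10, 3))
            _, rmsd = superpose(X, Y)
            assert rmsd == pytest.approx(quaternion_rmsd(X, Y), abs=1e-9)

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5.0), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            superpose(line, line)


class TestPcaCombined:
    def test_identical_trajectories_give_identical_clouds(self):
        traj, _ = gen_peptide_traj(60, seed=6, label="a")
        ref = traj.ca_coords(True)[0]
        res = pca_combined(traj, traj, ref)
        half = traj.n_frames
        assert np.allclose(res.projections[:half], res.projections[half:], atol=1e-9)

    def test_single_direction_of_variation(self):
        base, _ = gen_peptide_traj(1, seed=7)
        shift = np.linspace(-1, 1, 40)
        # move one interior CA along x only, so the Calpha extraction
        # sees a single direction of variation
        ca_positions = [i for i, (r, _, a) in enumerate(base.atoms) if a == "CA"]
        coords = np.repeat(base.coords, 40, axis=0)
        coords[:, ca_positions[2], 0] += shift
        traj = PeptideTrajectory(coords=coords, atoms=base.atoms)
        ref = traj.ca_coords(True)[0]
        res = pca_combined(traj, traj, ref)
        assert res.explained_fraction[0] > 0.99

    def test_components_orthonormal_and_variance_accounted(self):
        ta, _ = gen_peptide_traj(80, seed=8, label="wt")
        tb, _ = gen_peptide_traj(80, [broad_leucine_like()] * 8, seed=9, label="mut")
        ref = ta.ca_coords(True)[0]
        res = pca_combined(ta, tb, ref)
        G = res.components @ res.components.T
        assert np.allclose(G, np.eye(G.shape[0]), atol=1e-9)
        assert np.all(np.diff(res.explained_variance) <= 1e-9)
        # eigenvalues account for the aligned coordinate variance
        assert res.explained_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        total_proj = res.projections.var(axis=0, ddof=1).sum()
        assert total_proj == pytest.approx(res.explained_variance.sum(), rel=1e-9)

    def test_broadened_ensemble_has_wider_projection_cloud(self):
        tight = [( _delta(-65.0), _delta(150.0) )] * 8
        ta, _ = gen_peptide_traj(100, tight, seed=10, label="narrow")
        tb, _ = gen_peptide_traj(100, [broad_leucine_like()] * 8, seed=11, label="broad")
        ref = ta.ca_coords(True)[0]
        res = pca_combined(ta, tb, ref)
        lab = np.array(res.labels)
        spread_a = np.trace(np.cov(res.projections[lab == "narrow"][:, :2].T))
        spread_b = np.trace(np.cov(res.projections[lab == "broad"][:, :2].T))
        assert spread_b > spread_a

    def test_atom_count_mismatch_rejected(self):
        ta, _ = gen_peptide_traj(5, n_residues=8, seed=0)
        tb, _ = gen_peptide_traj(5, n_residues=6, seed=0)
        with pytest.raises(ValueError):
            pca_combined(ta, tb, ta.ca_coords(True)[0])
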