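"""Superposition and PCA of coordinate fluctuations."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles
from scipy.spatial.transform import Rotation

from chanflux.essential_dynamics import (
    align_modes_to_reference,
    covariance_and_modes,
    cumulative_fluctuation_fraction,
    extreme_projections,
    project_frames,
    superpose_trajectory,
)
from chanflux.errors import ParameterError
from chanflux.synthetic import gen_harmonic_modes
from chanflux.trajectory_model import AtomRecord, TrajectoryView


def _view_from_coords(coords):
    atoms = [
        AtomRecord(atom_id=i, name="CA", element="C", residue_name="ALA",
                   residue_id=i + 1, chain_id="A")
        for i in range(coords.shape[1])
    ]
    return TrajectoryView(atoms, coords, np.arange(coords.shape[0], dtype=float))


class TestSuperposition:
    def test_pure_rotations_fit_to_zero_rmsd(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(-5, 5, size=(20, 3))
        rots = Rotation.random(6, random_state=np.random.RandomState(4))
        coords = np.stack([base @ R.T for R in rots.as_matrix()])
        fitted = superpose_trajectory(_view_from_coords(coords), "first_frame")
        rmsd = np.sqrt(((fitted.coords - fitted.coords[0]) ** 2).sum(-1).mean(-1))
        assert np.all(rmsd < 1e-6)

    def test_known_rotation_recovered(self):
        from chanflux.essential_dynamics import _kabsch

        rng = np.random.default_rng(5)
        base = rng.uniform(-5, 5, size=(15, 3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        # mobile frames were rotated by Rz^-1, so the fit must rotate by Rz^T
        R, t = _kabsch(base @ Rz.T, base)
        np.testing.assert_allclose(R, Rz.T, atol=1e-9)

    def test_fitting_is_idempotent(self):
        traj, _ = gen_harmonic_modes([2.0], n_atoms=12, n_frames=50, seed=6, rigid_noise=True)
        once = superpose_trajectory(traj, "mean")
        twice = superpose_trajectory(once, "mean")
        np.testing.assert_allclose(once.coords, twice.coords, atol=1e-6)


class TestModes:
    def test_single_mode_dominates(self):
        traj, _ = gen_harmonic_modes([3.0], n_atoms=10, n_frames=400, seed=7)
        modes = covariance_and_modes(traj)
        assert cumulative_fluctuation_fraction(modes, 1) > 0.999

    def test_static_trajectory_zero_spectrum(self):
        coords = np.repeat(np.random.default_rng(1).uniform(0, 5, (1, 8, 3)), 5, axis=0)
        modes = covariance_and_modes(_view_from_coords(coords))
        assert modes.eigenvalues.max() == pytest.approx(0.0, abs=1e-12)

    def test_planted_variance_ratio_and_subspace(self):
        traj, truth = gen_harmonic_modes([4.0, 1.0], n_atoms=30, n_frames=10_000, seed=11)
        fitted = superpose_trajectory(traj, "mean")
        modes = covariance_and_modes(fitted)
        ratio = modes.eigenvalues[0] / modes.eigenvalues[1]
        assert ratio == pytest.approx(4.0, rel=0.05)
        modes = align_modes_to_reference(modes, truth["mean"])
        ang = np.degrees(
            subspace_angles(truth["mode_vectors"], modes.eigenvectors[:, :2]).max()
        )
        assert ang <= 5.0

    def test_rigid_noise_leaves_spectrum_unchanged(self):
        clean, _ = gen_harmonic_modes([4.0, 1.0], n_atoms=20, n_frames=3000, seed=13)
        noisy, _ = gen_harmonic_modes(
            [4.0, 1.0], n_atoms=20, n_frames=3000, seed=13, rigid_noise=True
        )
        m_clean = covariance_and_modes(superpose_trajectory(clean, "mean"))
        m_noisy = covariance_and_modes(superpose_trajectory(noisy, "mean"))
        np.testing.assert_allclose(
            m_clean.eigenvalues[:2], m_noisy.eigenvalues[:2], rtol=1e-6
        )

    def test_total_variance_conserved(self):
        traj, _ = gen_harmonic_modes([2.0, 1.0, 0.5], n_atoms=15, n_frames=2000, seed=17)
        fitted = superpose_trajectory(traj, "mean")
        modes = covariance_and_modes(fitted)
        X = fitted.coords.reshape(fitted.n_frames, -1)
        msf = ((X - X.mean(0)) ** 2).sum(1).mean()
        assert modes.total_variance == pytest.approx(msf, rel=1e-6)

    def test_frame_permutation_invariance(self):
        traj, _ = gen_harmonic_modes([2.0, 1.0], n_atoms=10, n_frames=500, seed=19)
        perm = np.random.default_rng(0).permutation(traj.n_frames)
        shuffled = _view_from_coords(traj.coords[perm])
        np.testing.assert_allclose(
            covariance_and_modes(traj).eigenvalues,
            covariance_and_modes(shuffled).eigenvalues,
            atol=1e-9,
        )

    def test_concatenated_trajectories_pool_frames(self):
        t1, _ = gen_harmonic_modes([2.0], n_atoms=8, n_frames=200, seed=23)
        modes = covariance_and_modes([t1, t1])
        assert modes.n_frames == 400


class TestFractionsAndExtremes:
    def test_all_modes_fraction_is_one(self):
        traj, _ = gen_harmonic_modes([2.0, 1.0], n_atoms=8, n_frames=300, seed=29)
        modes = covariance_and_modes(traj)
        assert cumulative_fluctuation_fraction(modes, len(modes.eigenvalues)) == 1.0

    def test_planted_spectrum_closed_form(self):
        traj, _ = gen_harmonic_modes([4.0, 1.0], n_atoms=20, n_frames=8000, seed=31)
        modes = covariance_and_modes(traj)
        assert cumulative_fluctuation_fraction(modes, 1) == pytest.approx(0.8, abs=0.02)

    def test_k_out_of_range(self):
        traj, _ = gen_harmonic_modes([1.0], n_atoms=5, n_frames=50, seed=37)
        modes = covariance_and_modes(traj)
        with pytest.raises(ParameterError):
            cumulative_fluctuation_fraction(modes, 0)

    def test_mean_projects_to_zero_and_extremes_antisymmetric(self):
        traj, truth = gen_harmonic_modes([3.0], n_atoms=10, n_frames=1000, seed=41)
        modes = covariance_and_modes(traj)
        mean_view = _view_from_coords(
            np.repeat(modes.mean_coords.reshape(1, -1, 3), 2, axis=0)
        )
        assert np.allclose(project_frames(modes, mean_view, 0), 0.0, atol=1e-9)
        lo, hi = extreme_projections(modes, traj, 0, quantile=2.0)
        mean = modes.mean_coords.reshape(-1, 3)
        np.testing.assert_allclose(lo - mean, -(hi - mean), atol=1e-9)

    def test_extreme_frames_match_generator_extremes(self):
        traj, truth = gen_harmonic_modes([3.0], n_atoms=10, n_frames=1000, seed=43)
        modes = covariance_and_modes(traj)
        lo, hi = extreme_projections(modes, traj, 0)
        amps = truth["amplitudes"][:, 0]
        expected = {int(np.argmin(amps)), int(np.argmax(amps))}
        got = set()
        for frame in (lo, hi):
            got.add(int(np.argmin(((traj.coords - frame) ** 2).sum(-1).sum(-1))))
        assert got == expected
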