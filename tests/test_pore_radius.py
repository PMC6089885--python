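"""Maximal-inscribed-sphere pore radii vs analytic and grid oracles."""

import numpy as np
import pytest

from chanflux.errors import EmptySliceError, ParameterError
from chanflux.pore_radius import (
    grid_search_radius_at_z,
    max_inscribed_radius_at_z,
    radius_profile_frame,
    temporal_radius_profile,
)
from chanflux.synthetic import gen_pore_geometry
from chanflux.trajectory_model import ChannelGeometry


def _ring(radius=5.0, n=12, z=0.0):
    ang = np.arange(n) * 2 * np.pi / n
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.full(n, z)])


@pytest.fixture
def narrow_geom():
    # search bound 2*cutoff stays inside a 5 Å ring wall
    return ChannelGeometry(axis=(0, 0, 1.0), origin=(0, 0, 0.0), lateral_cutoff=2.0)


class TestSliceOptimizer:
    def test_ring_analytic_inscribed_circle(self, narrow_geom):
        s = max_inscribed_radius_at_z(_ring(5.0), np.full(12, 1.5), narrow_geom, 0.0, rng_seed=1)
        assert s.radius == pytest.approx(3.5, abs=0.05)
        assert np.hypot(*s.center_xy) < 0.05

    def test_axis_blocking_atom_occludes(self):
        # search bound (2 x 0.5 Å) keeps the centre within the blocked core
        tight = ChannelGeometry(axis=(0, 0, 1.0), origin=(0, 0, 0.0), lateral_cutoff=0.5)
        pos = np.array([[0.0, 0.0, 0.0]])
        s = max_inscribed_radius_at_z(pos, np.array([1.5]), tight, 0.0, rng_seed=0)
        assert s.radius <= 0.0

    def test_empty_slice_raises(self, narrow_geom):
        with pytest.raises(EmptySliceError):
            max_inscribed_radius_at_z(_ring(5.0, z=40.0), np.full(12, 1.5), narrow_geom, 0.0)

    def test_matches_grid_search_oracle(self, narrow_geom):
        rng = np.random.default_rng(4)
        for seed in range(3):
            n = 30
            r = rng.uniform(3.5, 6.5, n)
            a = rng.uniform(0, 2 * np.pi, n)
            pos = np.column_stack(
                [r * np.cos(a), r * np.sin(a), rng.uniform(-3, 3, n)]
            )
            vdw = rng.uniform(1.2, 1.9, n)
            opt = max_inscribed_radius_at_z(pos, vdw, narrow_geom, 0.0, rng_seed=seed)
            ref = grid_search_radius_at_z(pos, vdw, narrow_geom, 0.0, resolution=0.02)
            assert opt.radius == pytest.approx(ref.radius, abs=0.05)

    def test_vdw_inflation_shrinks_radius_uniformly(self, narrow_geom):
        pos, vdw = _ring(5.0), np.full(12, 1.5)
        base = max_inscribed_radius_at_z(pos, vdw, narrow_geom, 0.0, rng_seed=2)
        fat = max_inscribed_radius_at_z(pos, vdw + 0.3, narrow_geom, 0.0, rng_seed=2)
        assert base.radius - fat.radius == pytest.approx(0.3, abs=0.02)


class TestFrameProfiles:
    def test_cylinder_profile_is_flat(self):
        traj, geom, _ = gen_pore_geometry(lambda z: 4.0, seed=1)
        prof = radius_profile_frame(
            traj.coords[0], traj.vdw_radii, geom, z_step=3.0, rng_seed=5
        )
        radii = np.array([s.radius for s in prof])
        np.testing.assert_allclose(radii, 4.0, atol=0.05)

    def test_hourglass_waist_located(self):
        hour = lambda z: 5.0 - 2.5 * np.exp(-((z - 10.0) ** 2) / (2 * 2.0**2))
        traj, geom, _ = gen_pore_geometry(hour, seed=2)
        prof = radius_profile_frame(
            traj.coords[0], traj.vdw_radii, geom, z_step=1.0, rng_seed=3
        )
        radii = [s.radius for s in prof]
        zs = [s.z for s in prof]
        assert zs[int(np.argmin(radii))] == pytest.approx(10.0, abs=1.0)
        assert min(radii) == pytest.approx(2.5, abs=0.05)

    def test_deterministic_given_seed(self):
        traj, geom, _ = gen_pore_geometry(lambda z: 4.0, seed=1)
        a = radius_profile_frame(traj.coords[0], traj.vdw_radii, geom, z_step=5.0, rng_seed=7)
        b = radius_profile_frame(traj.coords[0], traj.vdw_radii, geom, z_step=5.0, rng_seed=7)
        assert [s.radius for s in a] == [s.radius for s in b]

    def test_rotation_translation_invariance(self):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("zx", [30, 15], degrees=True).as_matrix()
        base, geom, _ = gen_pore_geometry(lambda z: 4.0, seed=6)
        moved, geom2, _ = gen_pore_geometry(
            lambda z: 4.0, rotation=rot, translation=np.array([5.0, -3.0, 8.0]), seed=6
        )
        pa = radius_profile_frame(base.coords[0], base.vdw_radii, geom, z_step=5.0, rng_seed=1)
        pb = radius_profile_frame(moved.coords[0], moved.vdw_radii, geom2, z_step=5.0, rng_seed=1)
        np.testing.assert_allclose(
            [s.radius for s in pa], [s.radius for s in pb], atol=0.05
        )


class TestTemporalProfiles:
    def test_rigid_cylinder_identical_time_bins(self):
        traj, geom, _ = gen_pore_geometry(lambda z: 4.0, seed=1, n_frames=8)
        # frames every 10 ps -> rescale times so the run spans 4 "ns"
        traj.times = traj.times * 50.0  # 500 ps spacing
        prof = temporal_radius_profile(
            traj, geom, monomers=["all"], snapshot_stride_ps=500.0,
            time_bin_ns=2.0, z_step=5.0, rng_seed=1, n_restarts=1,
        )
        assert prof.radius.shape[0] == 2
        np.testing.assert_allclose(prof.radius[0], prof.radius[1], atol=0.05)

    def test_radius_switch_between_bins(self):
        t1, geom, _ = gen_pore_geometry(lambda z: 4.0, seed=3, n_frames=4)
        t2, _, _ = gen_pore_geometry(lambda z: 6.0, seed=3, n_frames=4)
        # walls widen from radius 4 to 6 at the 2 ns mark
        n = min(t1.n_atoms, t2.n_atoms)
        coords = np.concatenate(
            [t1.coords[:, :n, :], t2.coords[:, :n, :]], axis=0
        )
        view = type(t1)(t1.atoms[:n], coords, np.arange(8) * 500.0)
        prof = temporal_radius_profile(
            view, geom, monomers=["all"], snapshot_stride_ps=500.0,
            time_bin_ns=2.0, z_step=10.0, rng_seed=2, n_restarts=1,
        )
        assert np.all(prof.radius[0] < prof.radius[1])

    def test_two_monomer_average(self):
        t1, geom, _ = gen_pore_geometry(lambda z: 4.0, seed=5, n_frames=5)
        t5, _, _ = gen_pore_geometry(lambda z: 5.0, seed=5, n_frames=5)
        atoms = [
            type(t1.atoms[0])(
                atom_id=i, name=a.name, element=a.element,
                residue_name=a.residue_name, residue_id=a.residue_id,
                chain_id=("A" if i < t1.n_atoms else "B"), vdw_radius=a.vdw_radius,
            )
            for i, a in enumerate(t1.atoms + t5.atoms)
        ]
        coords = np.concatenate([t1.coords, t5.coords], axis=1)
        view = type(t1)(atoms, coords, np.arange(5) * 500.0)
        prof = temporal_radius_profile(
            view, geom, monomers=["chain A", "chain B"], snapshot_stride_ps=500.0,
            time_bin_ns=2.0, z_step=10.0, rng_seed=3, n_restarts=1,
        )
        np.testing.assert_allclose(prof.radius, 4.5, atol=0.05)

    def test_empty_monomer_list_rejected(self):
        traj, geom, _ = gen_pore_geometry(lambda z: 4.0, seed=1, n_frames=4)
        traj.times = traj.times * 50.0
        with pytest.raises(ParameterError):
            temporal_radius_profile(traj, geom, monomers=[])
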