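"""Trajectory container, selections, geometry and water classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chanflux.errors import (
    ConsistencyError,
    FormatError,
    GeometryError,
    ParameterError,
    SelectionError,
)
from chanflux.synthetic import gen_pore_geometry, gen_single_file_channel
from chanflux.trajectory_model import (
    ChannelGeometry,
    classify_channel_waters,
    define_channel_geometry,
    load_trajectory,
    write_trajectory,
)

from conftest import rigid_transform


class TestLoading:
    def test_multimodel_pdb_identity_load(self, tmp_path, water_view):
        view = water_view(np.linspace(-20, 20, 3)[:, None] * np.ones((1, 5)))
        pdb = tmp_path / "w.pdb"
        write_trajectory(view, pdb)
        back = load_trajectory(pdb)
        assert back.n_atoms == 5
        assert back.n_frames == 3

    def test_empty_selection_raises(self, tmp_path, water_view):
        view = water_view(np.zeros((2, 3)))
        pdb = tmp_path / "w.pdb"
        write_trajectory(view, pdb)
        with pytest.raises(SelectionError):
            load_trajectory(pdb, selection="name XYZ")

    def test_missing_file_raises_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            load_trajectory(tmp_path / "nope.pdb")

    def test_pdb_dcd_round_trip_matches_generator(self, tmp_path):
        traj, _, _ = gen_single_file_channel(n_waters=8, n_frames=20, seed=4)
        write_trajectory(traj, tmp_path / "f.pdb", tmp_path / "f.dcd")
        back = load_trajectory(tmp_path / "f.pdb", tmp_path / "f.dcd")
        assert back.n_frames == traj.n_frames
        # PDB/DCD store single precision; 1e-3 Å covers format rounding
        np.testing.assert_allclose(back.coords, traj.coords, atol=1e-3)

    def test_irregular_times_rejected(self, water_view):
        view = water_view(np.zeros((3, 2)))
        with pytest.raises(ConsistencyError):
            type(view)(view.atoms, view.coords, np.array([0.0, 1.0, 3.0]))


class TestGeometry:
    def test_fixed_z_centroid_origin(self, water_view):
        view = water_view(np.zeros((2, 4)))
        g = define_channel_geometry(view, "all", "fixed_z", -15, 15, 6)
        np.testing.assert_allclose(g.origin, (0, 0, 0), atol=1e-12)
        np.testing.assert_allclose(g.axis, (0, 0, 1))
        assert g.pore_length_L == 30

    def test_translated_anchor_shifts_origin(self, water_view):
        view = water_view(5.0 * np.ones((1, 3)))
        view.coords[:, :, 0] = 2.0
        view.coords[:, :, 1] = 3.0
        g = define_channel_geometry(view, "all")
        np.testing.assert_allclose(g.origin, (2, 3, 5), atol=1e-12)
        assert g.axial(np.array([2.0, 3.0, 15.0])) == pytest.approx(10.0)

    def test_principal_axis_recovers_tilted_cylinder(self):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xy", [20, 35], degrees=True).as_matrix()
        traj, _, truth = gen_pore_geometry(lambda z: 4.0, rotation=rot, seed=3)
        g = define_channel_geometry(traj, "all", "principal_axis")
        cosang = abs(np.dot(g.axis, truth["axis"]))
        assert np.degrees(np.arccos(min(cosang, 1.0))) < 1.0

    def test_bad_bounds_raise(self, water_view):
        view = water_view(np.zeros((1, 3)))
        with pytest.raises(ParameterError):
            define_channel_geometry(view, "all", z_lower=5, z_upper=-5)

    def test_collinear_anchor_principal_axis_degenerate(self, water_view):
        view = water_view(np.array([[0.0, 1.0, 2.0]]))  # 3 collinear atoms
        with pytest.raises(GeometryError):
            define_channel_geometry(view, "all", "principal_axis")


class TestClassification:
    def test_center_inside_boundary_outside(self, geom, water_view):
        view = water_view(np.array([[0.0, 15.1]]))
        inside = classify_channel_waters(view, geom, "all")
        assert list(inside[0]) == [0]

    def test_matches_brute_force_cylinder_test(self, geom):
        rng = np.random.default_rng(7)
        pts = rng.uniform(-25, 25, size=(1, 100, 3))
        from chanflux.trajectory_model import AtomRecord, TrajectoryView

        atoms = [
            AtomRecord(atom_id=i, name="OW", element="O", residue_name="HOH",
                       residue_id=i + 1, chain_id="W")
            for i in range(100)
        ]
        view = TrajectoryView(atoms, pts, np.array([0.0]))
        got = set(classify_channel_waters(view, geom, "all")[0])
        expected = {
            i
            for i, p in enumerate(pts[0])
            if geom.z_lower <= p[2] <= geom.z_upper
            and np.hypot(p[0], p[1]) <= geom.lateral_cutoff
        }
        assert got == expected

    def test_rigid_transform_invariance(self, geom):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-25, 25, size=(2, 50, 3))
        moved, rot, shift = rigid_transform(pts, seed=9)
        g2 = ChannelGeometry(
            axis=tuple(rot @ np.array(geom.axis)),
            origin=tuple(rot @ np.array(geom.origin) + shift),
            z_lower=geom.z_lower, z_upper=geom.z_upper,
            lateral_cutoff=geom.lateral_cutoff,
        )
        np.testing.assert_allclose(geom.axial(pts), g2.axial(moved), atol=1e-6)
        np.testing.assert_allclose(geom.lateral(pts), g2.lateral(moved), atol=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.5, max_value=10.0), st.floats(min_value=0.1, max_value=8.0))
    def test_membership_monotone_in_lateral_cutoff(self, cutoff, delta):
        rng = np.random.default_rng(11)
        pts = rng.uniform(-20, 20, size=(1, 40, 3))
        from chanflux.trajectory_model import AtomRecord, TrajectoryView

        atoms = [
            AtomRecord(atom_id=i, name="OW", element="O", residue_name="HOH",
                       residue_id=i + 1, chain_id="W")
            for i in range(40)
        ]
        view = TrajectoryView(atoms, pts, np.array([0.0]))
        small = ChannelGeometry(axis=(0, 0, 1.0), origin=(0, 0, 0.0), lateral_cutoff=cutoff)
        large = ChannelGeometry(axis=(0, 0, 1.0), origin=(0, 0, 0.0), lateral_cutoff=cutoff + delta)
        s = set(classify_channel_waters(view, small, "all")[0])
        l = set(classify_channel_waters(view, large, "all")[0])
        assert s <= l
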