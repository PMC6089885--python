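import numpy as np
import pytest

from chanflux.trajectory_model import AtomRecord, ChannelGeometry, TrajectoryView


@pytest.fixture
def geom():
    return ChannelGeometry(axis=(0.0, 0.0, 1.0), origin=(0.0, 0.0, 0.0))


@pytest.fixture
def water_view():
    """Three waters on a 5-frame trajectory with simple axial motion."""

    def make(z_paths, dt=1.0, lateral=0.0):
        z = np.asarray(z_paths, dtype=float)  # (frames, waters)
        n_frames, n_waters = z.shape
        coords = np.zeros((n_frames, n_waters, 3))
        coords[:, :, 0] = lateral
        coords[:, :, 2] = z
        atoms = [
            AtomRecord(atom_id=i, name="OW", element="O", residue_name="HOH",
                       residue_id=i + 1, chain_id="W")
            for i in range(n_waters)
        ]
        return TrajectoryView(atoms, coords, np.arange(n_frames) * dt)

    return make


def rigid_transform(coords, seed=0):
    """Random rotation + translation applied to (..., 3) coordinates."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
    shift = np.random.RandomState(seed + 1).uniform(-30, 30, 3)
    return coords @ rot.T + shift, rot, shift
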