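"""Essential dynamics: PCA of Cartesian coordinate fluctuations.

Frames are first rigid-body superposed (optimal rotation + translation,
Kabsch) onto a reference — either the first frame or the iteratively
fitted mean structure — so that only internal motions remain.  The
covariance matrix of the 3N fitted coordinates is then diagonalised; its
eigenvectors are the collective modes, sorted by decreasing variance.
The cumulative fluctuation fraction of the first k modes quantifies how
much of the total mean-square fluctuation they explain, and extreme
projections along a mode give the two most displaced structures for
visualising the motion.

Mass weighting is off: all atoms (Cα by default in the drivers) weigh
equally.  Multiple trajectories of equivalent monomers may be
concatenated before the covariance step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GeometryError, InsufficientDataError, ParameterError
from .trajectory_model import TrajectoryView


@dataclass
class ModeSet:
    """Eigen-decomposition of the coordinate covariance."""

    mean_coords: np.ndarray  # (3N,)
    eigenvalues: np.ndarray  # Å², descending
    eigenvectors: np.ndarray  # (3N, n_modes), columns orthonormal
    n_frames: int

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation so that mobile @ R.T + t ≈ reference."""
    mc, rc = mobile.mean(0), reference.mean(0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    R = rot.as_matrix()
    return R, rc - mc @ R.T


def superpose_trajectory(
    traj: TrajectoryView,
    reference: str = "mean",
    fit_selection="all",
) -> TrajectoryView:
    """Least-squares superpose every frame onto a common reference.

    ``reference='first_frame'`` fits to frame 0; ``'mean'`` performs two
    passes (fit to frame 0, recompute the mean, refit to the mean), which
    converges for the small-amplitude fluctuations PCA assumes.  The fit
    uses ``fit_selection`` atoms; the transform is applied to all atoms.
    """
    if traj.n_frames < 2:
        raise InsufficientDataError("need at least 2 frames to superpose")
    fit_idx = traj.select_indices(fit_selection)
    if fit_idx.size < 3:
        raise GeometryError("fit selection needs at least 3 atoms")
    spread = traj.coords[0, fit_idx] - traj.coords[0, fit_idx].mean(0)
    if np.linalg.matrix_rank(spread, tol=1e-8) < 2:
        raise GeometryError("fit selection is (nearly) collinear")

    def _fit_all(coords: np.ndarray, ref_fit: np.ndarray) -> np.ndarray:
        out = np.empty_like(coords)
        for f in range(coords.shape[0]):
            R, t = _kabsch(coords[f, fit_idx], ref_fit)
            out[f] = coords[f] @ R.T + t
        return out

    if reference == "first_frame":
        fitted = _fit_all(traj.coords, traj.coords[0, fit_idx])
    elif reference == "mean":
        fitted = _fit_all(traj.coords, traj.coords[0, fit_idx])
        fitted = _fit_all(fitted, fitted[:, fit_idx].mean(axis=0))
    else:
        raise ParameterError(f"unknown reference {reference!r}")
    return traj.with_coords(fitted)


def covariance_and_modes(
    trajs: TrajectoryView | Sequence[TrajectoryView],
    atom_selection="all",
) -> ModeSet:
    """Diagonalise the Cartesian covariance of (concatenated) trajectories.

    Input frames are assumed superposed.  Trajectories of equivalent
    monomers may be passed as a sequence and are concatenated frame-wise.
    """
    if isinstance(trajs, TrajectoryView):
        trajs = [trajs]
    blocks = []
    for tr in trajs:
        idx = tr.select_indices(atom_selection)
        blocks.append(tr.coords[:, idx, :].reshape(tr.n_frames, -1))
    X = np.vstack(blocks)
    if X.shape[0] < 2:
        raise InsufficientDataError("need at least 2 frames for a covariance")
    mean = X.mean(axis=0)
    C = np.cov(X, rowvar=False, ddof=0)
    C = np.atleast_2d(C)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    return ModeSet(
        mean_coords=mean,
        eigenvalues=evals,
        eigenvectors=evecs[:, order],
        n_frames=X.shape[0],
    )


def align_modes_to_reference(modes: ModeSet, ref_coords: np.ndarray) -> ModeSet:
    """Re-express a ModeSet in the frame of a reference structure.

    The superposition frame is arbitrary up to a global rotation and
    translation; to compare eigenvectors with modes defined in another
    frame (a planted ground truth, or another system's average), the
    mean structure is Kabsch-aligned onto ``ref_coords`` (shape (N, 3))
    and the same rotation is applied to every eigenvector.  Eigenvalues
    are untouched.
    """
    n_atoms = modes.mean_coords.shape[0] // 3
    ref = np.asarray(ref_coords, dtype=float).reshape(n_atoms, 3)
    mean = modes.mean_coords.reshape(n_atoms, 3)
    R, t = _kabsch(mean, ref)
    new_mean = mean @ R.T + t
    vecs = modes.eigenvectors.reshape(n_atoms, 3, -1)
    new_vecs = np.einsum("ij,ajk->aik", R, vecs).reshape(3 * n_atoms, -1)
    return ModeSet(
        mean_coords=new_mean.reshape(-1),
        eigenvalues=modes.eigenvalues.copy(),
        eigenvectors=new_vecs,
        n_frames=modes.n_frames,
    )


def cumulative_fluctuation_fraction(modes: ModeSet, k: int) -> float:
    """Fraction of total mean-square fluctuation carried by the first k modes."""
    if not (1 <= k <= len(modes.eigenvalues)):
        raise ParameterError(f"k must be in [1, {len(modes.eigenvalues)}]")
    total = modes.eigenvalues.sum()
    if total <= 0:
        return 0.0
    return float(modes.eigenvalues[:k].sum() / total)


def project_frames(
    modes: ModeSet, traj: TrajectoryView, mode_index: int, atom_selection="all"
) -> np.ndarray:
    """Projection of each frame's displacement onto one mode (Å)."""
    idx = traj.select_indices(atom_selection)
    X = traj.coords[:, idx, :].reshape(traj.n_frames, -1)
    if X.shape[1] != modes.mean_coords.shape[0]:
        raise ParameterError("selection does not match the mode dimensionality")
    if not (0 <= mode_index < modes.eigenvectors.shape[1]):
        raise ParameterError("mode_index out of range")
    return (X - modes.mean_coords) @ modes.eigenvectors[:, mode_index]


def extreme_projections(
    modes: ModeSet,
    traj: TrajectoryView,
    mode_index: int = 0,
    quantile: float | None = None,
    atom_selection="all",
) -> Tuple[np.ndarray, np.ndarray]:
    """Structures at the two extremes of the motion along one mode.

    With ``quantile=None`` the actual frames of minimum and maximum
    projection are returned; otherwise idealised reconstructions
    mean ± quantile·σ along the mode.  Shapes are (N, 3).
    """
    proj = project_frames(modes, traj, mode_index, atom_selection)
    n_atoms = modes.mean_coords.shape[0] // 3
    if quantile is None:
        idx = traj.select_indices(atom_selection)
        lo = traj.coords[int(np.argmin(proj))][idx]
        hi = traj.coords[int(np.argmax(proj))][idx]
        return lo, hi
    sigma = float(np.sqrt(modes.eigenvalues[mode_index]))
    v = modes.eigenvectors[:, mode_index]
    lo = (modes.mean_coords - quantile * sigma * v).reshape(n_atoms, 3)
    hi = (modes.mean_coords + quantile * sigma * v).reshape(n_atoms, 3)
    return lo, hi
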