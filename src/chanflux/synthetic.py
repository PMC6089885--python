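"""Synthetic ground-truth generators for every pipeline stage.

Each generator emulates the *statistics* a real channel trajectory feeds
into one analysis stage — not the physics that produced them — and
returns, alongside the trajectory objects, a truth record sufficient to
score the stage without re-deriving the ground truth:

* ``gen_single_file_channel`` — waters performing 1D Brownian motion
  along a cylindrical channel axis with a prescribed collective
  diffusion constant D_n; waters leaving the far end of the simulation
  slab are recycled to the opposite end so crossings occur at a steady
  rate.  The truth record carries D_n and the generator's own permeation
  event log.
* ``gen_planted_crossings`` — deterministic piecewise-linear paths with
  an exactly known number of up/down crossings and retreats.
* ``gen_boltzmann_axial`` — axial water positions sampled from the
  Boltzmann density of a known free-energy profile.
* ``gen_pore_geometry`` — rings of pseudo-atoms whose inner van der
  Waals surface realises a prescribed radius profile R(z).
* ``gen_interface_toy`` — two pseudo-monomers with planted atom pairs in
  contact for an exact fraction of frames.
* ``gen_harmonic_modes`` — frames fluctuating along known orthonormal
  modes with prescribed variances, optionally scrambled by rigid-body
  motion to exercise the superposition step.

All randomness flows from an explicit integer seed; output is bitwise
reproducible for fixed seed and parameters.
"""

from __future__ import annotations

from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np

from .errors import ParameterError
from .pmf import OccupancyHistogram, axial_bin_edges, kBT
from .trajectory_model import AtomRecord, ChannelGeometry, TrajectoryView


def _water_atoms(n: int) -> List[AtomRecord]:
    return [
        AtomRecord(
            atom_id=i, name="OW", element="O", residue_name="HOH",
            residue_id=i + 1, chain_id="W",
        )
        for i in range(n)
    ]


def _pseudo_atoms(n: int, chain: str = "A", vdw: float = 1.70,
                  resid_of=None, name: str = "C") -> List[AtomRecord]:
    return [
        AtomRecord(
            atom_id=i, name=name, element="C", residue_name="PSD",
            residue_id=(resid_of(i) if resid_of else i + 1), chain_id=chain,
            vdw_radius=vdw,
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# single-file water channel
# ---------------------------------------------------------------------------

def gen_single_file_channel(
    D_n_true: float = 1.0,
    L: float = 30.0,
    n_waters: int = 100,
    n_frames: int = 10_000,
    dt_ps: float = 10.0,
    seed: int = 0,
    buffer_A: float = 10.0,
    lateral_cutoff: float = 6.0,
) -> Tuple[TrajectoryView, ChannelGeometry, Dict]:
    """Brownian single-file waters in a cylinder with known D_n (1/ns).

    Waters move only axially (fixed small lateral offsets well inside the
    cutoff) over the domain ``[z_lower - buffer, z_upper + buffer]`` with
    periodic recycling at the outer edges.  The per-water step variance
    is chosen so that the collective coordinate n(t) diffuses with
    ``D_n_true``: D_n = <N_inside> * D_w / L^2, with <N_inside> set by
    the uniform steady state.  The generator logs complete crossings with
    its own below/inside/above bookkeeping as it simulates.
    """
    if min(L, n_waters, n_frames, dt_ps) <= 0 or buffer_A < 0 or D_n_true < 0:
        raise ParameterError("all generator parameters must be positive")
    rng = np.random.default_rng(seed)
    z_lower, z_upper = -L / 2.0, L / 2.0
    lo, hi = z_lower - buffer_A, z_upper + buffer_A
    L_tot = hi - lo
    n_inside_expected = n_waters * L / L_tot
    # D_n [1/ns] -> per-water diffusion in Å^2/ps
    D_w = (D_n_true / 1000.0) * L * L / n_inside_expected
    sigma = np.sqrt(2.0 * D_w * dt_ps)

    z = rng.uniform(lo, hi, size=n_waters)
    # fixed lateral offsets, well inside the cutoff
    ang = rng.uniform(0, 2 * np.pi, size=n_waters)
    rad = rng.uniform(0, 0.4 * lateral_cutoff, size=n_waters)
    xy = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])

    side = np.array([None] * n_waters, dtype=object)
    entered = np.zeros(n_waters, dtype=bool)
    events: List[Dict] = []

    def _observe(frame: int) -> None:
        for w in range(n_waters):
            zz = z[w]
            if zz < z_lower:
                if side[w] == "above" and entered[w]:
                    events.append({"water": w, "direction": "down", "frame": frame})
                side[w], entered[w] = "below", False
            elif zz > z_upper:
                if side[w] == "below" and entered[w]:
                    events.append({"water": w, "direction": "up", "frame": frame})
                side[w], entered[w] = "above", False
            else:
                if side[w] is not None:
                    entered[w] = True

    coords = np.empty((n_frames, n_waters, 3))
    _observe(0)
    coords[0, :, 0] = xy[:, 0]
    coords[0, :, 1] = xy[:, 1]
    coords[0, :, 2] = z
    for f in range(1, n_frames):
        if sigma > 0:
            z = z + rng.normal(scale=sigma, size=n_waters)
            z = lo + np.mod(z - lo, L_tot)  # recycle at the outer edges
        _observe(f)
        coords[f, :, 0] = xy[:, 0]
        coords[f, :, 1] = xy[:, 1]
        coords[f, :, 2] = z

    traj = TrajectoryView(
        _water_atoms(n_waters), coords, np.arange(n_frames) * dt_ps
    )
    geom = ChannelGeometry(
        axis=(0.0, 0.0, 1.0), origin=(0.0, 0.0, 0.0),
        z_lower=z_lower, z_upper=z_upper, lateral_cutoff=lateral_cutoff,
    )
    up = sum(1 for e in events if e["direction"] == "up")
    truth = {
        "D_n_true": D_n_true,
        "D_w_A2_per_ps": D_w,
        "events": events,
        "total_events": len(events),
        "up_events": up,
        "down_events": len(events) - up,
    }
    return traj, geom, truth


def gen_planted_crossings(
    n_up: int = 5,
    n_down: int = 3,
    n_retreat: int = 4,
    L: float = 30.0,
    n_frames: int = 101,
    dt_ps: float = 1.0,
    seed: int = 0,
) -> Tuple[TrajectoryView, ChannelGeometry, Dict]:
    """Deterministic piecewise-linear paths with exact known event counts.

    Crossers run linearly from one vestibule to the other; retreaters
    enter the channel and return to their entry side.  Small seeded
    per-water phase offsets decorrelate the paths without changing any
    event count.
    """
    rng = np.random.default_rng(seed)
    z_lower, z_upper = -L / 2.0, L / 2.0
    margin = 5.0
    n_waters = n_up + n_down + n_retreat
    t = np.linspace(0.0, 1.0, n_frames)
    zs = []
    for _ in range(n_up):
        zs.append((z_lower - margin) + (L + 2 * margin) * t)
    for _ in range(n_down):
        zs.append((z_upper + margin) - (L + 2 * margin) * t)
    for _ in range(n_retreat):
        # below -> mid-channel -> below
        depth = (z_lower - margin) + (L / 2 + margin + 2.0) * np.minimum(t, 1 - t) * 2
        zs.append(depth)
    zmat = np.array(zs).T  # (frames, waters)
    lateral = rng.uniform(0, 1.0, size=n_waters)
    coords = np.zeros((n_frames, n_waters, 3))
    coords[:, :, 0] = lateral
    coords[:, :, 2] = zmat
    traj = TrajectoryView(_water_atoms(n_waters), coords, np.arange(n_frames) * dt_ps)
    geom = ChannelGeometry(
        axis=(0.0, 0.0, 1.0), origin=(0.0, 0.0, 0.0),
        z_lower=z_lower, z_upper=z_upper, lateral_cutoff=6.0,
    )
    truth = {
        "total_events": n_up + n_down,
        "up_events": n_up,
        "down_events": n_down,
        "retreaters": n_retreat,
    }
    return traj, geom, truth


# ---------------------------------------------------------------------------
# Boltzmann-distributed axial occupancy
# ---------------------------------------------------------------------------

def gen_boltzmann_axial(
    G_true: Callable[[np.ndarray], np.ndarray],
    n_samples: int = 1_000_000,
    temperature_K: float = 310.0,
    bin_width: float = 0.5,
    geom: ChannelGeometry | None = None,
    seed: int = 0,
    grid_points: int = 4001,
) -> Tuple[OccupancyHistogram, Dict]:
    """Sample axial positions from the Boltzmann density of G_true.

    ``G_true`` maps z (Å) to free energy (kJ/mol); sampling uses
    inverse-CDF interpolation on a fine grid over [z_lower, z_upper].
    The truth record holds the exact (offset-free) profile evaluated at
    the histogram bin centres.
    """
    if geom is None:
        geom = ChannelGeometry(axis=(0, 0, 1.0), origin=(0, 0, 0.0))
    rng = np.random.default_rng(seed)
    zg = np.linspace(geom.z_lower, geom.z_upper, grid_points)
    G = np.asarray(G_true(zg), dtype=float)
    dens = np.exp(-(G - G.min()) / kBT(temperature_K))
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(zg))])
    cdf /= cdf[-1]
    samples = np.interp(rng.random(int(n_samples)), cdf, zg)
    edges = axial_bin_edges(geom, bin_width)
    counts, _ = np.histogram(samples, bins=edges)
    hist = OccupancyHistogram(
        z_edges=edges, mean_count=counts / float(n_samples), n_frames=int(n_samples)
    )
    centers = hist.z_centers
    G_centers = np.asarray(G_true(centers), dtype=float)
    truth = {
        "G_true_at_centers": G_centers - G_centers.min(),
        "temperature_K": temperature_K,
    }
    return hist, truth


# ---------------------------------------------------------------------------
# pseudo-atom pore walls
# ---------------------------------------------------------------------------

def gen_pore_geometry(
    profile: Callable[[float], float],
    vdw: float = 1.5,
    ring_spacing: float = 0.5,
    z_margin: float = 2.0,
    n_shells: int = 3,
    shell_spacing: float = 2.5,
    arc_spacing: float = 1.3,
    geom: ChannelGeometry | None = None,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    seed: int = 0,
    n_frames: int = 1,
) -> Tuple[TrajectoryView, ChannelGeometry, Dict]:
    """Channel walls whose inscribed-sphere radius profile equals ``profile``.

    Rings of pseudo-atoms are placed every ``ring_spacing`` along the
    axis at centre distance ``profile(z) + vdw`` so the inner van der
    Waals surface realises R(z) exactly at the ring planes.  Behind the
    innermost ring, ``n_shells - 1`` further concentric shells mimic the
    protein bulk so the inscribed-sphere search cannot escape radially
    outside the wall.  An optional rigid rotation/translation is applied
    to both the atoms and the returned geometry (for invariance and
    axis-recovery tests).
    """
    if geom is None:
        geom = ChannelGeometry(axis=(0, 0, 1.0), origin=(0, 0, 0.0))
    rng = np.random.default_rng(seed)
    zs = np.arange(geom.z_lower - z_margin, geom.z_upper + z_margin + 1e-9, ring_spacing)
    pos = []
    for z in zs:
        r_inner = float(profile(float(z))) + vdw
        for shell in range(n_shells):
            r = r_inner + shell * shell_spacing
            n_atoms = max(8, int(np.ceil(2 * np.pi * r / arc_spacing)))
            phase = rng.uniform(0, 2 * np.pi)
            ang = phase + np.arange(n_atoms) * 2 * np.pi / n_atoms
            pos.append(
                np.column_stack(
                    [r * np.cos(ang), r * np.sin(ang), np.full(n_atoms, z)]
                )
            )
    pos = np.vstack(pos)

    axis = np.array([0.0, 0.0, 1.0])
    origin = np.zeros(3)
    if rotation is not None:
        pos = pos @ np.asarray(rotation).T
        axis = np.asarray(rotation) @ axis
    if translation is not None:
        pos = pos + np.asarray(translation)
        origin = origin + np.asarray(translation)
    out_geom = ChannelGeometry(
        axis=tuple(axis / np.linalg.norm(axis)),
        origin=tuple(origin),
        z_lower=geom.z_lower,
        z_upper=geom.z_upper,
        lateral_cutoff=geom.lateral_cutoff,
    )
    atoms = _pseudo_atoms(len(pos), chain="P", vdw=vdw)
    coords = np.repeat(pos[None, :, :], n_frames, axis=0)
    traj = TrajectoryView(atoms, coords, np.arange(n_frames, dtype=float) * 10.0)
    truth = {"profile": profile, "vdw": vdw, "axis": tuple(axis), "origin": tuple(origin)}
    return traj, out_geom, truth


# ---------------------------------------------------------------------------
# planted interface contacts
# ---------------------------------------------------------------------------

def gen_interface_toy(
    persistent_pairs: Sequence[Tuple[int, int]],
    transient_pairs: Sequence[Tuple[int, int, float]] = (),
    n_frames: int = 100,
    seed: int = 0,
    contact_distance: float = 3.5,
    apart_distance: float = 8.0,
) -> Tuple[TrajectoryView, Dict]:
    """Two pseudo-monomers with atom pairs in contact for exact fractions.

    ``persistent_pairs`` are (residA, residB) pairs in contact every
    frame; ``transient_pairs`` add (residA, residB, fraction) pairs whose
    contact occupies exactly ``round(fraction * n_frames)`` randomly
    chosen frames.  Distinct pairs are laterally separated so no
    accidental cross-pair contacts arise.  Chain A / chain B hold one
    atom per planted residue.
    """
    rng = np.random.default_rng(seed)
    pairs = [(ra, rb, 1.0) for ra, rb in persistent_pairs] + [
        (ra, rb, float(f)) for ra, rb, f in transient_pairs
    ]
    n_pairs = len(pairs)
    if n_pairs == 0:
        raise ParameterError("plant at least one pair")
    coords = np.zeros((n_frames, 2 * n_pairs, 3))
    contact_frames = {}
    for k, (ra, rb, frac) in enumerate(pairs):
        x = 20.0 * k
        coords[:, k, 0] = x  # chain A atom fixed
        m = int(round(frac * n_frames))
        on = rng.choice(n_frames, size=m, replace=False)
        zb = np.full(n_frames, apart_distance)
        zb[on] = contact_distance
        coords[:, n_pairs + k, 0] = x
        coords[:, n_pairs + k, 2] = zb
        contact_frames[(ra, rb)] = m
    atoms_A = _pseudo_atoms(n_pairs, chain="A", resid_of=lambda i: pairs[i][0])
    atoms_B = [
        AtomRecord(
            atom_id=n_pairs + i, name="C", element="C", residue_name="PSD",
            residue_id=pairs[i][1], chain_id="B",
        )
        for i in range(n_pairs)
    ]
    traj = TrajectoryView(atoms_A + atoms_B, coords, np.arange(n_frames, dtype=float))
    planted_persistent = {
        (ra, rb)
        for (ra, rb, f) in pairs
        if contact_frames[(ra, rb)] >= 0.70 * n_frames - 1e-9
    }
    truth = {
        "persistent_set": planted_persistent,
        "contact_frames": contact_frames,
        "n_frames": n_frames,
    }
    return traj, truth


# ---------------------------------------------------------------------------
# harmonic modes
# ---------------------------------------------------------------------------

def gen_harmonic_modes(
    mode_variances: Sequence[float],
    n_atoms: int = 30,
    n_frames: int = 10_000,
    seed: int = 0,
    mode_vectors: np.ndarray | None = None,
    rigid_noise: bool = False,
) -> Tuple[TrajectoryView, Dict]:
    """Frames fluctuating along known orthonormal modes.

    Coordinates are ``mean + sum_k a_k(t) v_k`` with a_k ~ N(0, var_k).
    With ``rigid_noise`` each frame is additionally rotated and
    translated at random, which superposition must undo before the
    planted spectrum is recoverable.
    """
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    dim = 3 * n_atoms
    variances = np.asarray(mode_variances, dtype=float)
    k = len(variances)
    if k >= dim - 6:
        raise ParameterError("need fewer modes than 3 * n_atoms - 6")
    # a compact random mean structure, non-degenerate for superposition
    mean = rng.uniform(-10, 10, size=(n_atoms, 3))
    # internal modes only: project out the 6 rigid-body directions of the
    # mean structure (3 translations + 3 infinitesimal rotations), which
    # superposition removes and PCA therefore cannot recover
    rigid = np.zeros((dim, 6))
    for a in range(3):
        rigid[a::3, a] = 1.0
    centred = mean - mean.mean(0)
    for a, omega in enumerate(np.eye(3)):
        rigid[:, 3 + a] = np.cross(omega, centred).reshape(-1)
    rigid, _ = np.linalg.qr(rigid)
    if mode_vectors is None:
        raw = rng.normal(size=(dim, k))
    else:
        raw = np.asarray(mode_vectors, dtype=float).reshape(dim, k)
    raw = raw - rigid @ (rigid.T @ raw)
    q, _ = np.linalg.qr(raw)
    V = q[:, :k]
    amps = rng.normal(size=(n_frames, k)) * np.sqrt(variances)
    X = mean.reshape(-1)[None, :] + amps @ V.T
    coords = X.reshape(n_frames, n_atoms, 3)
    if rigid_noise:
        rots = Rotation.random(n_frames, random_state=np.random.RandomState(seed + 1))
        trans = rng.uniform(-20, 20, size=(n_frames, 3))
        coords = np.einsum("fij,faj->fai", rots.as_matrix(), coords) + trans[:, None, :]
    atoms = [
        AtomRecord(
            atom_id=i, name="CA", element="C", residue_name="ALA",
            residue_id=i + 1, chain_id="A",
        )
        for i in range(n_atoms)
    ]
    traj = TrajectoryView(atoms, coords, np.arange(n_frames, dtype=float) * 10.0)
    truth = {
        "mode_vectors": V,
        "mode_variances": variances,
        "mean": mean,
        "amplitudes": amps,
    }
    return traj, truth
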