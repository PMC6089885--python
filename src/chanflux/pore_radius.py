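"""Pore radius profiling by maximal inscribed sphere.

At each axial position z the pore radius is the radius of the largest
sphere centred in the plane at z that touches no atom's van der Waals
surface:

    R(z) = max_{p in plane(z)}  min_i ( |p - a_i| - vdw_i )

The in-plane maximisation uses simulated annealing with multiple starts
(the previous slice's centre plus random restarts) followed by a
Nelder-Mead polish; with the search centre constrained to twice the
lateral cutoff around the pore axis.  The radius may be negative where
the pore is fully occluded.

Per-snapshot profiles are aggregated into *temporal* profiles: a 2D map
of mean radius over (time bin x axial position), with snapshots taken
every 10 ps and averaged in 2 ns bins by default, optionally pooled over
several monomers.  Slices are plane-constrained along the fixed channel
axis; a curved 3D centreline is not propagated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy.optimize import minimize

from .errors import EmptySliceError, InsufficientDataError, ParameterError
from .trajectory_model import ChannelGeometry, TrajectoryView

#: wall atoms further than this from the slice plane are ignored (Å)
SLAB_HALF_WIDTH = 15.0
#: optimiser stops when the proposal step drops below this (Å)
STEP_TOL = 0.01


@dataclass
class PoreSlice:
    z: float
    center_xy: tuple
    radius: float
    converged: bool


@dataclass
class TemporalRadiusProfile:
    """Mean pore radius per (time bin, axial position); NaN where no data."""

    time_bin_edges: np.ndarray  # ns
    z_grid: np.ndarray  # Å
    radius: np.ndarray  # (n_time_bins, n_z)
    n_monomers_averaged: int


def _clearance(xy: np.ndarray, z: float, local_pos: np.ndarray, vdw: np.ndarray) -> float:
    """min_i (|p - a_i| - vdw_i) for p = (x, y, z) in the channel frame."""
    d = local_pos - np.array([xy[0], xy[1], z])
    return float(np.min(np.sqrt(np.einsum("ij,ij->i", d, d)) - vdw))


def max_inscribed_radius_at_z(
    wall_positions: np.ndarray,
    vdw_radii: np.ndarray,
    geom: ChannelGeometry,
    z: float,
    init_xy=None,
    rng_seed: int = 0,
    n_restarts: int = 3,
    initial_step: float = 1.0,
    cooling: float = 0.9,
) -> PoreSlice:
    """Largest sphere centred in the plane at axial position z.

    ``wall_positions`` are cartesian coordinates (Å) of the wall atoms
    (typically protein heavy atoms); ``vdw_radii`` their van der Waals
    radii.  Deterministic for a fixed ``rng_seed``.
    """
    local = geom.to_local(np.asarray(wall_positions, dtype=float))
    vdw = np.asarray(vdw_radii, dtype=float)
    near = np.abs(local[:, 2] - z) <= SLAB_HALF_WIDTH
    if not np.any(near):
        raise EmptySliceError(f"no wall atoms within {SLAB_HALF_WIDTH} Å of z = {z}")
    local, vdw = local[near], vdw[near]
    bound = 2.0 * geom.lateral_cutoff
    rng = np.random.default_rng(rng_seed)

    starts = []
    if init_xy is not None:
        starts.append(np.asarray(init_xy, dtype=float))
    else:
        starts.append(np.zeros(2))
    for _ in range(n_restarts):
        ang = rng.uniform(0, 2 * np.pi)
        rad = geom.lateral_cutoff * np.sqrt(rng.uniform())
        starts.append(np.array([rad * np.cos(ang), rad * np.sin(ang)]))

    best_xy, best_f = None, -np.inf
    for x0 in starts:
        xy = np.clip(x0, -bound, bound)
        f = _clearance(xy, z, local, vdw)
        step = initial_step
        while step >= STEP_TOL:
            for _ in range(10):
                cand = xy + rng.normal(scale=step, size=2)
                if np.linalg.norm(cand) > bound:
                    continue
                fc = _clearance(cand, z, local, vdw)
                # Metropolis acceptance with temperature tied to the step size
                if fc > f or rng.uniform() < np.exp((fc - f) / (0.1 * step)):
                    xy, f = cand, fc
            step *= cooling
        res = minimize(
            lambda p: -_clearance(p, z, local, vdw)
            + max(0.0, np.linalg.norm(p) - bound) * 100.0,
            xy,
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400},
        )
        fx = _clearance(res.x, z, local, vdw)
        if fx > f and np.linalg.norm(res.x) <= bound:
            xy, f = res.x, fx
        if f > best_f:
            best_xy, best_f = xy, f
    return PoreSlice(z=float(z), center_xy=tuple(best_xy), radius=best_f, converged=True)


def radius_profile_frame(
    wall_positions: np.ndarray,
    vdw_radii: np.ndarray,
    geom: ChannelGeometry,
    z_step: float = 0.5,
    rng_seed: int = 0,
    n_restarts: int = 3,
) -> List[PoreSlice]:
    """Pore slices from z_lower to z_upper at z_step for one frame.

    Each slice's optimisation starts from the previous slice's centre,
    which keeps the centreline continuous through constrictions.
    """
    if z_step <= 0:
        raise ParameterError("z_step must be positive")
    zs = np.arange(geom.z_lower, geom.z_upper + 1e-9, z_step)
    slices: List[PoreSlice] = []
    prev_xy = None
    for k, z in enumerate(zs):
        sl = max_inscribed_radius_at_z(
            wall_positions,
            vdw_radii,
            geom,
            float(z),
            init_xy=prev_xy,
            rng_seed=rng_seed + k,
            n_restarts=n_restarts,
        )
        prev_xy = sl.center_xy
        slices.append(sl)
    return slices


def temporal_radius_profile(
    traj: TrajectoryView,
    geom: ChannelGeometry,
    monomers: Sequence,
    snapshot_stride_ps: float = 10.0,
    time_bin_ns: float = 2.0,
    z_step: float = 0.5,
    rng_seed: int = 0,
    wall_filter: str = "heavy",
    n_restarts: int = 3,
) -> TemporalRadiusProfile:
    """2D (time bin x z) pore-radius map averaged over monomers.

    ``monomers`` is a list of atom selections, one per monomer channel;
    per-snapshot profiles of every monomer are pooled within each
    ``time_bin_ns`` bin.  Cells with no contributing snapshot are NaN.
    """
    if not monomers:
        raise ParameterError("monomer list must not be empty")
    span_ns = (traj.times[-1] - traj.times[0]) / 1000.0
    if span_ns + 1e-9 < time_bin_ns:
        raise InsufficientDataError(
            f"trajectory spans {span_ns:.3f} ns < one {time_bin_ns} ns bin"
        )
    dt = traj.dt_ps or snapshot_stride_ps
    stride = max(1, int(round(snapshot_stride_ps / dt)))
    frame_ids = np.arange(0, traj.n_frames, stride)
    zs = np.arange(geom.z_lower, geom.z_upper + 1e-9, z_step)
    n_bins = max(1, int(np.ceil(span_ns / time_bin_ns - 1e-9)))
    edges_ns = traj.times[0] / 1000.0 + np.arange(n_bins + 1) * time_bin_ns

    acc = np.zeros((n_bins, len(zs)))
    cnt = np.zeros((n_bins, len(zs)), dtype=int)
    for sel in monomers:
        sub = traj.subset(sel)
        if wall_filter:
            sub = sub.subset(wall_filter)
        vdw = sub.vdw_radii
        for f in frame_ids:
            t_ns = traj.times[f] / 1000.0
            b = min(n_bins - 1, int((t_ns - edges_ns[0]) / time_bin_ns))
            profile = radius_profile_frame(
                sub.coords[f], vdw, geom, z_step=z_step,
                rng_seed=rng_seed + 1000 * int(f), n_restarts=n_restarts,
            )
            acc[b] += [sl.radius for sl in profile]
            cnt[b] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return TemporalRadiusProfile(
        time_bin_edges=edges_ns,
        z_grid=zs,
        radius=mean,
        n_monomers_averaged=len(monomers),
    )


def grid_search_radius_at_z(
    wall_positions: np.ndarray,
    vdw_radii: np.ndarray,
    geom: ChannelGeometry,
    z: float,
    resolution: float = 0.02,
    extent: float | None = None,
) -> PoreSlice:
    """Brute-force dense grid search for the same objective.

    Exhaustive reference for validating the annealed optimiser; cost grows
    as (extent/resolution)^2 so keep slices small.
    """
    local = geom.to_local(np.asarray(wall_positions, dtype=float))
    vdw = np.asarray(vdw_radii, dtype=float)
    near = np.abs(local[:, 2] - z) <= SLAB_HALF_WIDTH
    if not np.any(near):
        raise EmptySliceError(f"no wall atoms within {SLAB_HALF_WIDTH} Å of z = {z}")
    local, vdw = local[near], vdw[near]
    if extent is None:
        extent = 2.0 * geom.lateral_cutoff
    ax = np.arange(-extent, extent + 1e-9, resolution)
    best_f, best_xy = -np.inf, (0.0, 0.0)
    for x in ax:  # row-chunked to bound memory; same disk as the optimiser
        ys = ax[x * x + ax * ax <= extent * extent]
        if ys.size == 0:
            continue
        pts = np.column_stack([np.full_like(ys, x), ys, np.full_like(ys, z)])
        d = np.sqrt(((pts[:, None, :] - local[None, :, :]) ** 2).sum(-1)) - vdw
        f = d.min(axis=1)
        j = int(np.argmax(f))
        if f[j] > best_f:
            best_f, best_xy = float(f[j]), (float(x), float(ys[j]))
    return PoreSlice(z=float(z), center_xy=best_xy, radius=best_f, converged=True)
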