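"""Trajectory container, atom selections and the channel coordinate system.

Everything downstream (permeation counting, PMFs, pore radii, contacts,
essential dynamics) operates on two objects defined here:

``TrajectoryView``
    an immutable, time-ordered stack of coordinate frames for a fixed set of
    atoms, with timestamps in ps and coordinates in Å;

``ChannelGeometry``
    the channel coordinate system: a unit axis (the membrane normal), an
    origin placed at the NPA region of the pore (so z = 0 at the NPA motif
    and the ar/R selectivity filter sits near +10 Å), two axial boundary
    planes and a lateral cutoff that together define "inside the channel".

File I/O goes through MDAnalysis; selections on files use the MDAnalysis
selection grammar.  In-memory views support a small selection grammar of
their own (``all``, ``element``, ``name``, ``resname``, ``chain``,
``resid``, ``heavy``, combined with ``and`` / prefixed with ``not``) which
is sufficient for synthetic fixtures and post-load filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    ConsistencyError,
    FormatError,
    GeometryError,
    ParameterError,
    SelectionError,
)

#: Bondi-style van der Waals radii in Å used for pore-radius and contact work.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}
DEFAULT_VDW = 1.70

_TIME_TOL_PS = 1e-6


def element_from_name(name: str) -> str:
    """Guess an element symbol from an atom name (PDB conventions)."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "C"
    first = stripped[0].upper()
    # two-letter elements we may meet in membrane-protein systems
    two = stripped[:2].upper()
    if two in ("CL", "NA", "MG", "FE", "ZN", "BR"):
        return two.capitalize()
    return first


@dataclass(frozen=True)
class AtomRecord:
    """Static description of one atom in a :class:`TrajectoryView`."""

    atom_id: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    vdw_radius: float = field(default=0.0)

    def __post_init__(self):
        if self.vdw_radius <= 0.0:
            object.__setattr__(
                self, "vdw_radius", VDW_RADII.get(self.element, DEFAULT_VDW)
            )

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


class TrajectoryView:
    """Time-ordered frames of labelled atom coordinates.

    Parameters
    ----------
    atoms:
        one :class:`AtomRecord` per atom, in coordinate order.
    coords:
        array of shape ``(n_frames, n_atoms, 3)`` in Å.
    times:
        frame timestamps in ps; strictly increasing and regularly spaced.
    """

    def __init__(self, atoms: Sequence[AtomRecord], coords, times):
        self.atoms = list(atoms)
        self.coords = np.asarray(coords, dtype=float)
        self.times = np.asarray(times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ConsistencyError(
                f"coords must have shape (n_frames, n_atoms, 3); got {self.coords.shape}"
            )
        if self.coords.shape[1] != len(self.atoms):
            raise ConsistencyError(
                f"{len(self.atoms)} atoms but frames carry "
                f"{self.coords.shape[1]} coordinate triples"
            )
        if self.coords.shape[0] != self.times.shape[0]:
            raise ConsistencyError("one timestamp per frame required")
        if len(self.times) > 1:
            dts = np.diff(self.times)
            if np.any(dts <= 0):
                raise ConsistencyError("frame times must be strictly increasing")
            if np.ptp(dts) > _TIME_TOL_PS:
                raise ConsistencyError(
                    "frame times must be regularly spaced within 1e-6 ps"
                )

    # -- basic introspection -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def dt_ps(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def atom_array(self, attr: str) -> np.ndarray:
        return np.array([getattr(a, attr) for a in self.atoms])

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    # -- selections ----------------------------------------------------------
    def select_indices(self, selection) -> np.ndarray:
        """Resolve a selection to atom indices.

        ``selection`` may be an index array/list (returned as-is), or a
        string in the mini-grammar described in the module docstring.
        """
        if not isinstance(selection, str):
            idx = np.asarray(selection, dtype=int)
            if idx.size == 0:
                raise SelectionError("explicit index selection is empty")
            return idx
        mask = self._selection_mask(selection)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise SelectionError(f"selection {selection!r} matched no atoms")
        return idx

    def _selection_mask(self, expr: str) -> np.ndarray:
        mask = np.ones(self.n_atoms, dtype=bool)
        for clause in expr.split(" and "):
            clause = clause.strip()
            negate = clause.startswith("not ")
            if negate:
                clause = clause[4:].strip()
            mask &= ~self._clause_mask(clause) if negate else self._clause_mask(clause)
        return mask

    def _clause_mask(self, clause: str) -> np.ndarray:
        tokens = clause.split()
        if not tokens:
            raise SelectionError("empty selection clause")
        kw, args = tokens[0].lower(), tokens[1:]
        if kw == "all":
            return np.ones(self.n_atoms, dtype=bool)
        if kw == "heavy":
            return np.array([a.is_heavy for a in self.atoms])
        if kw == "element":
            vals = {a.upper() for a in args}
            return np.array([a.element.upper() in vals for a in self.atoms])
        if kw == "name":
            vals = set(args)
            return np.array([a.name in vals for a in self.atoms])
        if kw == "resname":
            vals = set(args)
            return np.array([a.residue_name in vals for a in self.atoms])
        if kw in ("chain", "chainid", "segid"):
            vals = set(args)
            return np.array([a.chain_id in vals for a in self.atoms])
        if kw == "resid":
            ids = set()
            for a in args:
                if ":" in a:
                    lo, hi = a.split(":")
                    ids.update(range(int(lo), int(hi) + 1))
                else:
                    ids.add(int(a))
            return np.array([a.residue_id in ids for a in self.atoms])
        raise SelectionError(f"unknown selection keyword {kw!r}")

    def subset(self, selection) -> "TrajectoryView":
        idx = self.select_indices(selection)
        return TrajectoryView(
            [self.atoms[i] for i in idx], self.coords[:, idx, :], self.times
        )

    def with_coords(self, coords) -> "TrajectoryView":
        return TrajectoryView(self.atoms, coords, self.times)


@dataclass(frozen=True)
class ChannelGeometry:
    """Channel coordinate system: axis, origin and the "inside" region.

    ``z = 0`` is the origin (placed at the NPA motif); positive z points
    toward the extracellular side, where the ar/R selectivity filter sits
    near +10 Å.  A water is *inside* the channel when its axial coordinate
    lies in ``[z_lower, z_upper]`` (closed on both ends) and its distance
    from the axis is at most ``lateral_cutoff``.
    """

    axis: tuple
    origin: tuple
    z_lower: float = -15.0
    z_upper: float = 15.0
    lateral_cutoff: float = 6.0
    pore_length_L: float | None = None

    def __post_init__(self):
        ax = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(ax) - 1.0) > 1e-9:
            raise GeometryError("axis must be a unit vector")
        if not (self.z_lower < 0.0 < self.z_upper):
            raise ParameterError("require z_lower < 0 < z_upper")
        if self.lateral_cutoff <= 0:
            raise ParameterError("lateral_cutoff must be positive")
        if self.pore_length_L is None:
            object.__setattr__(self, "pore_length_L", self.z_upper - self.z_lower)
        elif self.pore_length_L <= 0:
            raise ParameterError("pore_length_L must be positive")
        object.__setattr__(self, "axis", tuple(ax))
        object.__setattr__(self, "origin", tuple(np.asarray(self.origin, dtype=float)))

    # -- coordinates ---------------------------------------------------------
    def axial(self, points: np.ndarray) -> np.ndarray:
        """Axial coordinate(s) z of cartesian point(s), in Å."""
        rel = np.asarray(points, dtype=float) - np.asarray(self.origin)
        return rel @ np.asarray(self.axis)

    def lateral(self, points: np.ndarray) -> np.ndarray:
        """Distance(s) from the pore axis, in Å."""
        rel = np.asarray(points, dtype=float) - np.asarray(self.origin)
        z = rel @ np.asarray(self.axis)
        perp = rel - np.multiply.outer(z, np.asarray(self.axis))
        return np.linalg.norm(perp, axis=-1)

    def basis(self) -> np.ndarray:
        """Right-handed orthonormal basis (u, v, axis) as rows."""
        ax = np.asarray(self.axis)
        helper = np.array([1.0, 0.0, 0.0])
        if abs(ax @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        u = np.cross(ax, helper)
        u /= np.linalg.norm(u)
        v = np.cross(ax, u)
        return np.vstack([u, v, ax])

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """Map cartesian points into the (u, v, z) channel frame."""
        rel = np.asarray(points, dtype=float) - np.asarray(self.origin)
        return rel @ self.basis().T


# ---------------------------------------------------------------------------
# loading and writing trajectories
# ---------------------------------------------------------------------------

def load_trajectory(topology_path, trajectory_path=None, selection="all",
                    dt_fallback_ps: float = 1.0) -> TrajectoryView:
    """Load a trajectory restricted to ``selection`` into a TrajectoryView.

    ``topology_path`` is a PDB (or other MDAnalysis-readable topology);
    ``trajectory_path`` is an XTC/DCD/TRR/multi-model-PDB coordinate file;
    when omitted the topology's own models are used.  ``selection`` is an
    MDAnalysis selection string.  Formats without timestamps (multi-model
    PDB) get synthetic times spaced ``dt_fallback_ps`` apart.
    """
    import MDAnalysis as mda

    topology_path = Path(topology_path)
    if not topology_path.exists():
        raise FormatError(f"topology file not found: {topology_path}")
    try:
        if trajectory_path is None:
            universe = mda.Universe(str(topology_path))
        else:
            trajectory_path = Path(trajectory_path)
            if not trajectory_path.exists():
                raise FormatError(f"trajectory file not found: {trajectory_path}")
            universe = mda.Universe(str(topology_path), str(trajectory_path))
    except FormatError:
        raise
    except Exception as exc:  # MDAnalysis raises assorted IO/ValueErrors
        msg = str(exc)
        if "atom" in msg.lower() and trajectory_path is not None:
            raise ConsistencyError(
                f"topology {topology_path} and trajectory {trajectory_path} "
                f"disagree: {msg}"
            ) from exc
        raise FormatError(f"could not read {topology_path}: {msg}") from exc

    try:
        group = universe.select_atoms(selection)
    except Exception as exc:
        raise SelectionError(f"bad selection {selection!r}: {exc}") from exc
    if len(group) == 0:
        raise SelectionError(f"selection {selection!r} matched no atoms")
    if trajectory_path is not None and hasattr(universe.trajectory, "n_atoms"):
        if universe.trajectory.n_atoms != len(universe.atoms):
            raise ConsistencyError(
                f"topology has {len(universe.atoms)} atoms but trajectory "
                f"frames carry {universe.trajectory.n_atoms}"
            )

    names = group.names
    try:
        elements = [str(e).capitalize() for e in group.elements]
    except Exception:
        elements = [element_from_name(n) for n in names]
    try:
        resnames = group.resnames
        resids = group.resids
    except Exception:
        resnames = ["UNK"] * len(group)
        resids = np.arange(1, len(group) + 1)
    try:
        segids = [str(s) for s in group.segids]
    except Exception:
        segids = ["A"] * len(group)

    atoms = [
        AtomRecord(
            atom_id=int(i),
            name=str(names[k]),
            element=elements[k] if elements[k] in VDW_RADII else elements[k][:1],
            residue_name=str(resnames[k]),
            residue_id=int(resids[k]),
            chain_id=segids[k],
        )
        for k, i in enumerate(group.ix)
    ]

    frames, times = [], []
    for ts in universe.trajectory:
        frames.append(group.positions.astype(float).copy())
        times.append(float(ts.time))
    coords = np.stack(frames)
    times = np.asarray(times)
    if len(times) > 1 and (np.any(np.diff(times) <= 0) or np.ptp(np.diff(times)) > _TIME_TOL_PS):
        times = np.arange(len(frames), dtype=float) * dt_fallback_ps
    return TrajectoryView(atoms, coords, times)


def write_trajectory(traj: TrajectoryView, pdb_path, dcd_path=None) -> None:
    """Write a TrajectoryView as a PDB topology plus optional DCD coordinates.

    With ``dcd_path=None`` all frames are written as PDB models.
    """
    import MDAnalysis as mda

    n = traj.n_atoms
    universe = mda.Universe.empty(
        n,
        n_residues=len({(a.chain_id, a.residue_id) for a in traj.atoms}),
        atom_resindex=_residue_index(traj.atoms),
        trajectory=True,
    )
    universe.add_TopologyAttr("names", [a.name for a in traj.atoms])
    universe.add_TopologyAttr("elements", [a.element for a in traj.atoms])
    res_keys = _unique_residues(traj.atoms)
    universe.add_TopologyAttr("resnames", [rn for (_, _, rn) in res_keys])
    universe.add_TopologyAttr("resids", [rid for (_, rid, _) in res_keys])
    universe.add_TopologyAttr("segids", sorted({c for (c, _, _) in res_keys}) or ["A"])
    universe.atoms.positions = traj.coords[0]

    pdb_path = Path(pdb_path)
    if dcd_path is None:
        with mda.Writer(str(pdb_path), multiframe=True, n_atoms=n) as w:
            for frame in traj.coords:
                universe.atoms.positions = frame
                w.write(universe.atoms)
        return
    universe.atoms.positions = traj.coords[0]
    with mda.Writer(str(pdb_path), n_atoms=n) as w:
        w.write(universe.atoms)
    with mda.Writer(str(dcd_path), n_atoms=n) as w:
        for frame in traj.coords:
            universe.atoms.positions = frame
            w.write(universe.atoms)


def _residue_index(atoms: Sequence[AtomRecord]) -> np.ndarray:
    keys = _unique_residues(atoms)
    lookup = {(c, rid): k for k, (c, rid, _) in enumerate(keys)}
    return np.array([lookup[(a.chain_id, a.residue_id)] for a in atoms])


def _unique_residues(atoms: Sequence[AtomRecord]):
    seen, keys = set(), []
    for a in atoms:
        key = (a.chain_id, a.residue_id)
        if key not in seen:
            seen.add(key)
            keys.append((a.chain_id, a.residue_id, a.residue_name))
    return keys


# ---------------------------------------------------------------------------
# channel geometry construction and water classification
# ---------------------------------------------------------------------------

def define_channel_geometry(
    traj: TrajectoryView,
    anchor_selection,
    axis_mode: str = "fixed_z",
    z_lower: float = -15.0,
    z_upper: float = 15.0,
    lateral_cutoff: float = 6.0,
) -> ChannelGeometry:
    """Build the channel coordinate system from anchor atoms.

    The origin is the centroid of the anchor atoms (e.g. the NPA-motif
    backbone) averaged over all frames.  ``axis_mode='fixed_z'`` uses the
    global z axis (the membrane normal of the simulation box);
    ``'principal_axis'`` uses the leading principal axis of the pooled
    anchor coordinates, which suits tilted synthetic channels.
    """
    if z_lower >= z_upper:
        raise ParameterError("z_lower must be < z_upper")
    idx = traj.select_indices(anchor_selection)
    if idx.size < 3:
        raise GeometryError("anchor selection must resolve at least 3 atoms")
    anchor = traj.coords[:, idx, :].reshape(-1, 3)
    origin = anchor.mean(axis=0)

    if axis_mode == "fixed_z":
        axis = np.array([0.0, 0.0, 1.0])
    elif axis_mode == "principal_axis":
        centered = anchor - origin
        cov = centered.T @ centered / len(centered)
        evals, evecs = np.linalg.eigh(cov)
        if evals[-1] < 1e-12:
            raise GeometryError("anchor atoms are coincident")
        if evals[-2] < 1e-12 * evals[-1]:
            raise GeometryError("anchor atoms are collinear; axis fit is degenerate")
        axis = evecs[:, -1]
        if axis[2] < 0:
            axis = -axis
    else:
        raise ParameterError(f"unknown axis_mode {axis_mode!r}")
    return ChannelGeometry(
        axis=tuple(axis),
        origin=tuple(origin),
        z_lower=z_lower,
        z_upper=z_upper,
        lateral_cutoff=lateral_cutoff,
    )


def classify_channel_waters(
    traj: TrajectoryView, geom: ChannelGeometry, water_selection
) -> list:
    """Per-frame sets of water atom indices inside the channel.

    A water (represented by its oxygen) is inside at a frame iff
    ``z_lower <= z <= z_upper`` and its lateral distance from the axis is
    at most ``lateral_cutoff``.  Returns a list of index arrays, one per
    frame, indexing into ``traj.atoms``.
    """
    widx = traj.select_indices(water_selection)
    pos = traj.coords[:, widx, :]
    z = geom.axial(pos)
    lat = geom.lateral(pos)
    inside = (
        (z >= geom.z_lower) & (z <= geom.z_upper) & (lat <= geom.lateral_cutoff)
    )
    return [widx[inside[f]] for f in range(traj.n_frames)]
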