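"""Monomer-monomer interface contact maps and difference maps.

Two heavy atoms from different monomers are *in contact* when they sit
within 4.0 Å of each other in at least 70% of the trajectory frames.
Persistent atom pairs are aggregated to residue pairs; a residue-pair
*frequency* is its number of persistent atom pairs divided by the map's
maximum, so entries lie in [0, 1].  Difference maps subtract two maps
cell-by-cell on the union of residue pairs, after an optional residue
relabelling (e.g. a paralog alignment map) has been applied to the
second map.

Periodic-boundary images are ignored: the interfaces of interest are
intra-tetramer and never wrap the box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import InputError, InsufficientDataError, MappingError
from .trajectory_model import TrajectoryView


@dataclass(frozen=True)
class ContactCriteria:
    distance_cutoff: float = 4.0  # Å
    min_fraction: float = 0.70  # fraction of frames
    heavy_atoms_only: bool = True

    def __post_init__(self):
        if not (0 < self.min_fraction <= 1):
            raise InputError("min_fraction must be in (0, 1]")
        if self.distance_cutoff <= 0:
            raise InputError("distance_cutoff must be positive")


@dataclass
class ContactMatrix:
    """Residue-pair contact map for one monomer-monomer interface."""

    residues_A: List[int]
    residues_B: List[int]
    pair_counts: Dict[Tuple[int, int], int]  # persistent atom pairs per residue pair
    n_frames: int
    criteria: ContactCriteria
    normalization: float = field(init=False)

    def __post_init__(self):
        self.normalization = float(max(self.pair_counts.values(), default=1))

    def frequency(self, res_a: int, res_b: int) -> float:
        return self.pair_counts.get((res_a, res_b), 0) / self.normalization

    def is_persistent(self, res_a: int, res_b: int) -> bool:
        return self.pair_counts.get((res_a, res_b), 0) >= 1

    @property
    def persistent_pairs(self) -> Set[Tuple[int, int]]:
        return set(self.pair_counts)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "resA": a,
                "resB": b,
                "n_atom_pairs": c,
                "frequency": c / self.normalization,
                "persistent": True,
            }
            for (a, b), c in sorted(self.pair_counts.items())
        ]
        return pd.DataFrame(rows, columns=["resA", "resB", "n_atom_pairs", "frequency", "persistent"])


def frame_contacts(
    coords: np.ndarray,
    idx_A: np.ndarray,
    idx_B: np.ndarray,
    criteria: ContactCriteria = ContactCriteria(),
) -> Set[Tuple[int, int]]:
    """All cross-set atom pairs within the distance cutoff in one frame.

    Spatial indexing (kd-tree) is used but results are exact.  Returns
    pairs of *global* atom indices (i in A, j in B).
    """
    idx_A = np.asarray(idx_A, dtype=int)
    idx_B = np.asarray(idx_B, dtype=int)
    if np.intersect1d(idx_A, idx_B).size:
        raise InputError("atom sets A and B must be disjoint")
    tree = cKDTree(coords[idx_B])
    hits = tree.query_ball_point(coords[idx_A], r=criteria.distance_cutoff)
    return {
        (int(idx_A[i]), int(idx_B[j])) for i, js in enumerate(hits) for j in js
    }


def persistent_contact_map(
    traj: TrajectoryView,
    monomer_A,
    monomer_B,
    criteria: ContactCriteria = ContactCriteria(),
) -> ContactMatrix:
    """Residue-pair map of persistent atom contacts across an interface.

    The >= ``min_fraction`` occupancy criterion is applied per *atom*
    pair; each persistent atom pair then contributes one count to its
    residue pair.
    """
    if traj.n_frames < 10:
        raise InsufficientDataError("need at least 10 frames for contact statistics")
    idx_A = traj.select_indices(monomer_A)
    idx_B = traj.select_indices(monomer_B)
    if criteria.heavy_atoms_only:
        heavy = np.array([a.is_heavy for a in traj.atoms])
        idx_A = idx_A[heavy[idx_A]]
        idx_B = idx_B[heavy[idx_B]]
    if np.intersect1d(idx_A, idx_B).size:
        raise InputError("monomer selections overlap")

    pair_frames: Dict[Tuple[int, int], int] = {}
    for f in range(traj.n_frames):
        for pair in frame_contacts(traj.coords[f], idx_A, idx_B, criteria):
            pair_frames[pair] = pair_frames.get(pair, 0) + 1

    need = criteria.min_fraction * traj.n_frames
    resid = traj.atom_array("residue_id").astype(int)
    pair_counts: Dict[Tuple[int, int], int] = {}
    for (i, j), c in pair_frames.items():
        if c >= need - 1e-9:
            key = (int(resid[i]), int(resid[j]))
            pair_counts[key] = pair_counts.get(key, 0) + 1
    return ContactMatrix(
        residues_A=sorted({int(resid[i]) for i in idx_A}),
        residues_B=sorted({int(resid[j]) for j in idx_B}),
        pair_counts=pair_counts,
        n_frames=traj.n_frames,
        criteria=criteria,
    )


def contact_difference_map(
    map1: ContactMatrix,
    map2: ContactMatrix,
    residue_map: Dict[int, int] | None = None,
    residue_map_B: Dict[int, int] | None = None,
) -> pd.DataFrame:
    """Signed difference frequency(map1) - frequency(map2) per residue pair.

    ``residue_map`` / ``residue_map_B`` translate map2's row/column
    residue numbering into map1's coordinate system (identity when None),
    e.g. the paralog correspondence from a sequence alignment.  Missing
    pairs count as frequency 0.  Raises MappingError naming any map2
    residue that has no image under the map.
    """
    def _remap(pairs: Iterable[Tuple[int, int]]):
        if residue_map is None and residue_map_B is None:
            return {p: p for p in pairs}
        out, missing = {}, []
        for a, b in pairs:
            a2 = residue_map.get(a) if residue_map is not None else a
            b2 = residue_map_B.get(b) if residue_map_B is not None else b
            if a2 is None or b2 is None:
                missing.append((a, b))
            else:
                out[(a, b)] = (a2, b2)
        if missing:
            raise MappingError(f"unmappable residue pairs from map2: {missing}")
        return out

    f2 = {
        _remap(map2.pair_counts)[p]: map2.frequency(*p) for p in map2.pair_counts
    }
    f1 = {p: map1.frequency(*p) for p in map1.pair_counts}
    pairs = sorted(set(f1) | set(f2))
    return pd.DataFrame(
        {
            "resA": [p[0] for p in pairs],
            "resB": [p[1] for p in pairs],
            "delta_frequency": [f1.get(p, 0.0) - f2.get(p, 0.0) for p in pairs],
        }
    )
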