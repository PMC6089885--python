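"""Potential of mean force of channel water from axial occupancy.

The free-energy profile along the pore axis is obtained by Boltzmann
inversion of the average water occupancy per axial bin:

    G(z) = -k_B T ln <n(z)>

where <n(z)> is the mean number of in-channel waters per frame in the bin
at z.  At the simulation temperature of 310 K, k_B T = 2.577 kJ/mol.
Occupancy is additive, so profiles for several equivalent monomers are
merged at the occupancy level (frame-weighted pooling) before a single
inversion — not by averaging per-monomer PMFs.

Bins with zero occupancy have an undefined (NaN) free energy rather than
+inf; the default display convention shifts the defined minimum to zero,
so only free-energy *differences* are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    ConsistencyError,
    DegenerateInputError,
    InsufficientDataError,
    ParameterError,
)
from .trajectory_model import ChannelGeometry, TrajectoryView

#: Boltzmann constant in kJ/(mol K)
KB_KJ_PER_MOL_K = 0.0083144626


def kBT(temperature_K: float) -> float:
    return KB_KJ_PER_MOL_K * temperature_K


@dataclass
class OccupancyHistogram:
    """Mean water count per frame per axial bin."""

    z_edges: np.ndarray
    mean_count: np.ndarray
    n_frames: int

    def __post_init__(self):
        self.z_edges = np.asarray(self.z_edges, dtype=float)
        self.mean_count = np.asarray(self.mean_count, dtype=float)
        if len(self.mean_count) != len(self.z_edges) - 1:
            raise ConsistencyError("need one count per bin")
        if np.any(self.mean_count < 0):
            raise ConsistencyError("mean_count must be non-negative")

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])


@dataclass
class PMFProfile:
    """Free-energy profile G(z) in kJ/mol; NaN where occupancy was zero."""

    z_centers: np.ndarray
    G: np.ndarray
    temperature_K: float
    offset_convention: str  # "min_zero" or "raw"

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.G)

    def barrier_height(self) -> float:
        """Max minus min of the defined profile (offset-free)."""
        g = self.G[self.defined]
        return float(g.max() - g.min())


def axial_bin_edges(geom: ChannelGeometry, bin_width: float) -> np.ndarray:
    """Edges tiling [z_lower, z_upper] with (approximately) bin_width bins."""
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    n_bins = max(1, int(round((geom.z_upper - geom.z_lower) / bin_width)))
    return np.linspace(geom.z_lower, geom.z_upper, n_bins + 1)


def occupancy_histogram(
    traj: TrajectoryView,
    geom: ChannelGeometry,
    water_selection,
    bin_width: float = 0.5,
    frame_stride_ps: float = 10.0,
) -> OccupancyHistogram:
    """Histogram in-channel water positions along the axis.

    Frames are sampled every ``frame_stride_ps`` (snapshots every 10 ps by
    default); each water inside the channel adds one count to its z bin
    and ``mean_count`` is the per-frame average.
    """
    edges = axial_bin_edges(geom, bin_width)
    dt = traj.dt_ps or frame_stride_ps
    stride = max(1, int(round(frame_stride_ps / dt)))
    frame_ids = np.arange(0, traj.n_frames, stride)
    if frame_ids.size == 0:
        raise InsufficientDataError("no frames at the requested stride")
    widx = traj.select_indices(water_selection)
    pos = traj.coords[np.ix_(frame_ids, widx)]
    z = geom.axial(pos)
    lat = geom.lateral(pos)
    inside = (z >= geom.z_lower) & (z <= geom.z_upper) & (lat <= geom.lateral_cutoff)
    counts, _ = np.histogram(z[inside], bins=edges)
    return OccupancyHistogram(
        z_edges=edges,
        mean_count=counts / float(frame_ids.size),
        n_frames=int(frame_ids.size),
    )


def histogram_from_samples(
    z_samples: np.ndarray, geom: ChannelGeometry, bin_width: float = 0.5
) -> OccupancyHistogram:
    """Build an OccupancyHistogram directly from axial samples.

    Treats each sample as one water observation in one frame (n_frames =
    number of samples), which fixes only the irrelevant PMF offset.
    """
    edges = axial_bin_edges(geom, bin_width)
    z_samples = np.asarray(z_samples, dtype=float)
    if z_samples.size == 0:
        raise InsufficientDataError("no samples")
    counts, _ = np.histogram(z_samples, bins=edges)
    return OccupancyHistogram(
        z_edges=edges, mean_count=counts / float(z_samples.size),
        n_frames=int(z_samples.size),
    )


def pmf_from_occupancy(
    hist: OccupancyHistogram,
    temperature_K: float = 310.0,
    offset_convention: str = "min_zero",
) -> PMFProfile:
    """Boltzmann-invert an occupancy histogram: G = -k_B T ln <n>."""
    if offset_convention not in ("min_zero", "raw"):
        raise ParameterError(f"unknown offset convention {offset_convention!r}")
    occ = hist.mean_count
    if not np.any(occ > 0):
        raise DegenerateInputError("all bins have zero occupancy")
    with np.errstate(divide="ignore"):
        G = np.where(occ > 0, -kBT(temperature_K) * np.log(np.where(occ > 0, occ, 1.0)), np.nan)
    if offset_convention == "min_zero":
        G = G - np.nanmin(G)
    return PMFProfile(
        z_centers=hist.z_centers,
        G=G,
        temperature_K=temperature_K,
        offset_convention=offset_convention,
    )


def average_pmf_over_monomers(
    histograms: Sequence[OccupancyHistogram],
    temperature_K: float = 310.0,
    offset_convention: str = "min_zero",
) -> PMFProfile:
    """Merge occupancy across monomers, then invert once.

    Per-bin occupancies are pooled as frame-weighted averages (equivalent
    to concatenating the monomer trajectories), and the Boltzmann
    inversion is applied to the pooled occupancy.
    """
    if not histograms:
        raise InsufficientDataError("no histograms to merge")
    edges = histograms[0].z_edges
    for h in histograms[1:]:
        if len(h.z_edges) != len(edges) or np.any(np.abs(h.z_edges - edges) > 1e-9):
            raise ConsistencyError("histograms use different bin edges")
    total_frames = sum(h.n_frames for h in histograms)
    pooled = sum(h.mean_count * h.n_frames for h in histograms) / total_frames
    merged = OccupancyHistogram(z_edges=edges, mean_count=pooled, n_frames=total_frames)
    return pmf_from_occupancy(merged, temperature_K, offset_convention)
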