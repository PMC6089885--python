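"""Water permeation counting and collective-diffusion osmotic permeability.

Two complementary measures of single-channel water transport:

* **Complete permeation events** — a water permeates when its axial history
  runs ``below -> inside -> above`` (an *up* event) or the mirror image
  (*down*), with the inside passage satisfying the lateral criterion.  A
  water that enters the channel and retreats to its entry side records
  nothing.

* **Osmotic permeability** ``p_f = v_w * D_n`` — the collective-diffusion
  estimate.  The dimensionless collective coordinate n(t) accumulates the
  axial displacements of all in-channel waters divided by the pore length
  L; n advances by 1 per net single-file crossing.  D_n is the Einstein
  diffusion constant of n(t) from the slope of its mean-squared
  displacement, and v_w is the volume of one water molecule
  (18.015 g/mol / (0.997 g/cm^3 · N_A) = 2.99e-23 cm^3).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import List, Sequence, Tuple

import numpy as np

from .errors import ConsistencyError, InsufficientDataError, ParameterError
from .trajectory_model import ChannelGeometry, TrajectoryView

#: volume of a single water molecule at 0.997 g/cm^3, in cm^3
V_W_CM3 = 2.99e-23


class Region(IntEnum):
    """Axial/lateral classification of a water at one frame."""

    BELOW = 0
    INSIDE = 1
    ABOVE = 2
    OUTSIDE_LATERAL = 3


@dataclass
class AxialTrace:
    """Axial history of one water: z(t), lateral distance and region state."""

    water_id: int
    times: np.ndarray
    z: np.ndarray
    lateral: np.ndarray
    region_state: np.ndarray  # Region codes, int8


@dataclass(frozen=True)
class PermeationRecord:
    """One complete crossing by one water."""

    water_id: int
    direction: str  # "up" (below -> above) or "down"
    entry_time: float  # ps, first in-channel frame of the passage
    exit_time: float  # ps, frame at which the far side is reached


@dataclass
class CollectiveCoordinateSeries:
    """Cumulative collective coordinate n(t) with its pore length L."""

    times: np.ndarray
    n: np.ndarray
    pore_length_L: float


@dataclass
class PermeabilityResult:
    """Collective diffusion constant and the osmotic permeability it implies."""

    D_n: float  # 1/ns
    v_w: float  # cm^3
    p_f: float  # 10^-14 cm^3/s
    fit_window: Tuple[float, float]  # (tau_min, tau_max) in ps
    n_bins: int
    clamped: bool = False  # True when a negative fitted slope was clamped to 0


def extract_axial_traces(
    traj: TrajectoryView, geom: ChannelGeometry, water_selection
) -> List[AxialTrace]:
    """One AxialTrace per selected water oxygen.

    Region assignment per frame: ``below`` iff z < z_lower, ``above`` iff
    z > z_upper (decided by z alone outside the slab), otherwise ``inside``
    when the lateral criterion holds and ``outside_lateral`` when it fails.
    """
    widx = traj.select_indices(water_selection)
    pos = traj.coords[:, widx, :]
    z = geom.axial(pos)  # (frames, waters)
    lat = geom.lateral(pos)
    state = np.full(z.shape, Region.INSIDE, dtype=np.int8)
    state[z < geom.z_lower] = Region.BELOW
    state[z > geom.z_upper] = Region.ABOVE
    in_slab = (z >= geom.z_lower) & (z <= geom.z_upper)
    state[in_slab & (lat > geom.lateral_cutoff)] = Region.OUTSIDE_LATERAL
    return [
        AxialTrace(
            water_id=int(widx[w]),
            times=traj.times,
            z=z[:, w],
            lateral=lat[:, w],
            region_state=state[:, w],
        )
        for w in range(len(widx))
    ]


def count_permeation_events(
    traces: Sequence[AxialTrace],
) -> Tuple[List[PermeationRecord], int, int, int]:
    """Run the permeation finite-state machine over every trace.

    Returns ``(records, total, up, down)``.  An *up* event requires the
    state history below -> (inside)+ -> above with no intervening return
    to below; *down* is symmetric.  A lateral exit while in the slab
    resets the machine to the side matching the sign of z, so waters
    skirting the pore mouth are never counted.  Multiple events per water
    are allowed; ``total = up + down``.
    """
    records: List[PermeationRecord] = []
    up = down = 0
    ref_times = None
    for tr in traces:
        if ref_times is None:
            ref_times = tr.times
        elif len(tr.times) != len(ref_times) or np.any(
            np.abs(tr.times - ref_times) > 1e-9
        ):
            raise ConsistencyError("traces carry inconsistent timestamps")
        side = None  # last boundary side the water touched: "below"/"above"
        entry_time = None  # first inside frame since leaving `side`
        for t, zval, state in zip(tr.times, tr.z, tr.region_state):
            if state == Region.BELOW:
                if side == "above" and entry_time is not None:
                    records.append(
                        PermeationRecord(tr.water_id, "down", float(entry_time), float(t))
                    )
                    down += 1
                side, entry_time = "below", None
            elif state == Region.ABOVE:
                if side == "below" and entry_time is not None:
                    records.append(
                        PermeationRecord(tr.water_id, "up", float(entry_time), float(t))
                    )
                    up += 1
                side, entry_time = "above", None
            elif state == Region.INSIDE:
                if side is not None and entry_time is None:
                    entry_time = t
            else:  # OUTSIDE_LATERAL: reset to the side matching sign(z)
                side = "below" if zval < 0 else "above"
                entry_time = None
    return records, up + down, up, down


def collective_coordinate(
    traces: Sequence[AxialTrace], geom: ChannelGeometry
) -> CollectiveCoordinateSeries:
    """Accumulate n(t) = sum over steps of sum_i dz_i / L.

    A water contributes its axial displacement over a step only when it is
    inside the channel at both step endpoints; n(0) = 0.
    """
    L = geom.pore_length_L
    if L is None or L <= 0:
        raise ParameterError("pore_length_L must be positive")
    if not traces:
        return CollectiveCoordinateSeries(np.array([0.0]), np.array([0.0]), L)
    times = traces[0].times
    n_steps = len(times) - 1
    dn = np.zeros(n_steps)
    for tr in traces:
        inside = tr.region_state == Region.INSIDE
        both = inside[:-1] & inside[1:]
        dn[both] += (tr.z[1:] - tr.z[:-1])[both] / L
    n = np.concatenate([[0.0], np.cumsum(dn)])
    return CollectiveCoordinateSeries(times=times, n=n, pore_length_L=L)


def osmotic_permeability(
    series: CollectiveCoordinateSeries,
    bin_width_ps: float = 200.0,
    v_w: float = V_W_CM3,
    fit_fraction: float = 0.5,
) -> PermeabilityResult:
    """Estimate D_n and p_f from the collective coordinate.

    The series is split into contiguous windows of ``bin_width_ps``.
    Within each window the mean-squared displacement
    ``MSD(tau) = <(n(t+tau) - n(t))^2>`` is computed for lags from one
    frame up to ``fit_fraction`` of the window; the window-averaged MSD is
    fit by least squares through the origin, D_n = slope / 2, and
    ``p_f = v_w * D_n`` reported in 10^-14 cm^3/s.
    """
    times, n = series.times, series.n
    if len(times) < 2:
        raise InsufficientDataError("need at least 2 frames")
    dt = float(times[1] - times[0])
    win = max(2, int(round(bin_width_ps / dt)))
    n_windows = len(n) // win
    if n_windows < 5:
        raise InsufficientDataError(
            f"need at least 5 windows of {bin_width_ps} ps; have {n_windows}"
        )
    max_lag = max(1, int(win * fit_fraction))
    msd = np.zeros(max_lag)
    for w in range(n_windows):
        seg = n[w * win : (w + 1) * win]
        for lag in range(1, max_lag + 1):
            d = seg[lag:] - seg[:-lag]
            msd[lag - 1] += np.mean(d * d)
    msd /= n_windows
    taus = np.arange(1, max_lag + 1) * dt  # ps
    slope = float(np.dot(taus, msd) / np.dot(taus, taus))  # 1/ps
    clamped = slope < 0
    D_n_per_ps = max(slope, 0.0) / 2.0
    D_n = D_n_per_ps * 1000.0  # 1/ns
    # p_f [cm^3/s] = v_w [cm^3] * D_n [1/s]; report in units of 1e-14 cm^3/s
    p_f = v_w * (D_n * 1e9) / 1e-14
    return PermeabilityResult(
        D_n=D_n,
        v_w=v_w,
        p_f=p_f,
        fit_window=(float(taus[0]), float(taus[-1])),
        n_bins=n_windows,
        clamped=clamped,
    )
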