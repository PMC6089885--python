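#!/usr/bin/env python
"""Temporal pore-radius profiles of an open vs a constricted channel.

Builds pseudo-atom channel walls — a uniform open pore and an hourglass
with its waist at the selectivity-filter position (z = +10 Å) — and
profiles them with the maximal-inscribed-sphere search, then assembles a
temporal (time-bin x z) map for walls that widen mid-run.  Writes
results/pore_profiles.csv and results/pore_temporal.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from chanflux.pore_radius import radius_profile_frame, temporal_radius_profile
from chanflux.synthetic import gen_pore_geometry
from chanflux.trajectory_model import TrajectoryView

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

open_pore = lambda z: 4.0
hourglass = lambda z: 4.0 - 2.2 * np.exp(-((z - 10.0) ** 2) / (2 * 2.0**2))

rows = []
for label, profile in (("open", open_pore), ("constricted", hourglass)):
    traj, geom, _ = gen_pore_geometry(profile, seed=7)
    slices = radius_profile_frame(
        traj.coords[0], traj.vdw_radii, geom, z_step=1.0, rng_seed=3
    )
    for s in slices:
        rows.append({"channel": label, "z_A": s.z, "radius_A": s.radius,
                     "radius_true_A": profile(s.z)})
df = pd.DataFrame(rows)
df.to_csv(OUT / "pore_profiles.csv", index=False)

con = df[df.channel == "constricted"]
waist = con.loc[con.radius_A.idxmin()]
print(con.iloc[::4].to_string(index=False))
print(f"\nconstricted channel: waist radius {waist.radius_A:.2f} Å at "
      f"z = {waist.z_A:+.1f} Å (selectivity-filter position; planted 1.80 Å at +10)")
open_err = np.abs(df[df.channel == "open"].radius_A - 4.0).max()
flank_err = np.abs(con.radius_A - con.radius_true_A).max()
print(f"open channel: max |recovered - 4.0| = {open_err:.3f} Å")
print(f"constricted flanks deviate up to {flank_err:.2f} Å below profile(z): a "
      "sphere centred in the plane at z is clipped by the narrower rings above "
      "it where the profile changes steeply — inherent to plane-constrained "
      "slices, and why the waist itself (locally flat) is recovered exactly")

# temporal map: walls widen from the hourglass to the open pore at 2 ns
t_narrow, geom, _ = gen_pore_geometry(hourglass, seed=8, n_frames=4)
t_open, _, _ = gen_pore_geometry(open_pore, seed=8, n_frames=4)
n = min(t_narrow.n_atoms, t_open.n_atoms)
coords = np.concatenate([t_narrow.coords[:, :n], t_open.coords[:, :n]], axis=0)
view = TrajectoryView(t_narrow.atoms[:n], coords, np.arange(8) * 500.0)
prof = temporal_radius_profile(
    view, geom, monomers=["all"], snapshot_stride_ps=500.0, time_bin_ns=2.0,
    z_step=2.5, rng_seed=5, n_restarts=1,
)
long = pd.DataFrame(
    [{"time_bin_ns": 2 * b, "z_A": z, "radius_A": prof.radius[b, k]}
     for b in range(prof.radius.shape[0]) for k, z in enumerate(prof.z_grid)]
)
long.to_csv(OUT / "pore_temporal.csv", index=False)
at_sf = long[np.isclose(long.z_A, 10.0)]
print("\ntemporal profile at the z = +10 Å constriction:")
print(at_sf.to_string(index=False))
print("the constriction present in the first 2 ns bin disappears in the second, "
      "as in a channel whose selectivity filter widens")
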