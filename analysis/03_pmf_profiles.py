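#!/usr/bin/env python
"""Recover axial free-energy profiles by Boltzmann inversion of occupancy.

Samples 1e6 water positions under a 5 kJ/mol Gaussian barrier at the
selectivity-filter position (z = +10 Å), inverts the occupancy
histogram, and compares with the planted profile.  Also demonstrates the
merge-then-invert average over monomers: an "active" (no barrier) and a
"blocked" (5 kJ/mol) monomer pooled at the occupancy level.  Writes
results/pmf_profiles.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from chanflux.pmf import average_pmf_over_monomers, pmf_from_occupancy
from chanflux.synthetic import gen_boltzmann_axial

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

barrier = lambda z: 5.0 * np.exp(-((z - 10.0) ** 2) / (2 * 2.0**2))
flat = lambda z: np.zeros_like(np.asarray(z, dtype=float))

hist_b, truth = gen_boltzmann_axial(barrier, n_samples=1_000_000, seed=101)
hist_f, _ = gen_boltzmann_axial(flat, n_samples=1_000_000, seed=102)

blocked = pmf_from_occupancy(hist_b)
active = pmf_from_occupancy(hist_f)
merged = average_pmf_over_monomers([hist_b, hist_f])

df = pd.DataFrame({
    "z_center_A": blocked.z_centers,
    "G_blocked_kJ_mol": blocked.G,
    "G_active_kJ_mol": active.G,
    "G_merged_kJ_mol": merged.G,
    "G_true_blocked_kJ_mol": truth["G_true_at_centers"],
})
df.to_csv(OUT / "pmf_profiles.csv", index=False)

err = np.nanmax(np.abs(blocked.G - truth["G_true_at_centers"]))
print(df.iloc[::6].to_string(index=False))
print(f"\nblocked-monomer barrier: {blocked.barrier_height():.2f} kJ/mol "
      f"(planted 5.0; max abs error {err:.3f} kJ/mol)")
print(f"active-monomer barrier:  {active.barrier_height():.2f} kJ/mol (planted 0)")
print(f"merged two-monomer barrier: {merged.barrier_height():.2f} kJ/mol — "
      "pooling occupancy with an open channel lowers the apparent barrier, "
      "the signature expected when averaging active and blocked monomers")
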