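#!/usr/bin/env python
"""Essential dynamics of synthetic monomer fluctuations.

Generates harmonic coordinate fluctuations with a dominant slow mode
(variance ratio 4:1 plus a tail of minor modes), scrambles them with
rigid-body motion, then superposes, diagonalises the covariance and
reports the eigenvalue spectrum, cumulative fluctuation fractions and
the extreme structures along mode 1.  Writes results/ed_spectrum.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from chanflux.essential_dynamics import (
    covariance_and_modes,
    cumulative_fluctuation_fraction,
    extreme_projections,
    superpose_trajectory,
)
from chanflux.synthetic import gen_harmonic_modes

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

variances = [4.0, 1.0, 0.4, 0.25, 0.15, 0.1, 0.08, 0.06, 0.05, 0.04, 0.03, 0.02]
traj, truth = gen_harmonic_modes(
    variances, n_atoms=40, n_frames=10_000, seed=33, rigid_noise=True
)
fitted = superpose_trajectory(traj, "mean")
modes = covariance_and_modes(fitted)

k = len(variances)
df = pd.DataFrame({
    "mode": np.arange(1, k + 1),
    "eigenvalue_A2": modes.eigenvalues[:k],
    "planted_variance_A2": variances,
    "cumulative_fraction": [
        cumulative_fluctuation_fraction(modes, i) for i in range(1, k + 1)
    ],
})
df.to_csv(OUT / "ed_spectrum.csv", index=False)
print(df.to_string(index=False))

f1 = cumulative_fluctuation_fraction(modes, 1)
f10 = cumulative_fluctuation_fraction(modes, 10)
print(f"\nfirst mode carries {100 * f1:.1f}% of the fluctuation; "
      f"first 10 modes carry {100 * f10:.1f}% — the few-slow-modes structure "
      "typical of channel monomer dynamics")
lo, hi = extreme_projections(modes, fitted, 0)
amp = np.linalg.norm(hi - lo, axis=1).max()
print(f"extreme structures along mode 1 differ by up to {amp:.2f} Å per atom")
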