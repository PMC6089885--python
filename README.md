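# chanflux

Water-transport analysis for membrane-channel (aquaporin-style) MD
trajectories: permeation-event counting, collective-diffusion osmotic
permeability, occupancy-based free-energy profiles, temporal pore-radius
maps, monomer–monomer interface contact maps, essential dynamics, and
the group statistics and paralog sequence comparison that tie them
together.

## The scientific problem

Plant plasma-membrane aquaporins (PIPs) assemble as tetramers in which
each monomer is an independent water channel, yet neighbouring monomers
modulate each other: PIP1 channels that are nearly inactive in
homotetramers transport water abundantly when their TM4–TM5 face packs
against a PIP2 monomer's TM1–TM2 face.  Quantifying that modulation from
equilibrium MD requires a consistent battery of per-monomer analyses:

* **Permeation events** — a water permeates when its axial trajectory
  runs vestibule → pore → opposite vestibule.  A per-water finite-state
  machine counts complete crossings (both directions), ignoring waters
  that enter and retreat or that skirt the pore mouth laterally.
* **Osmotic permeability** (collective-diffusion method) —

  `n(t) = Σ_steps Σ_{i in pore} dz_i / L`,  `MSD(τ) = ⟨(n(t+τ) − n(t))²⟩ = 2 D_n τ`,  `p_f = v_w · D_n`

  where L is the pore length and v_w = 2.99 × 10⁻²³ cm³ the volume of a
  water molecule. n(t) advances by 1 per net single-file crossing, so
  D_n measures transport including the partial progress that discrete
  event counts miss.
* **PMF by Boltzmann inversion** — `G(z) = −k_B T ln⟨n(z)⟩` from the
  mean axial occupancy per bin (k_B T = 2.577 kJ/mol at 310 K), with
  occupancies of equivalent monomers pooled *before* inversion.
* **Pore radius** — HOLE-style maximal inscribed sphere per axial slice,
  assembled into 2D (time-bin × z) maps that show constrictions at the
  ar/R selectivity filter (≈ +10 Å above the NPA motif, which defines
  z = 0) appearing and disappearing over time.
* **Interface contacts** — heavy-atom pairs within 4.0 Å in ≥ 70% of
  frames, aggregated to residue pairs and compared across systems via
  signed difference maps (with paralog residue numbering mapped through
  a sequence alignment).
* **Essential dynamics** — PCA of Cartesian fluctuations after
  least-squares superposition; the leading eigenvectors are the
  dominant collective motions.

Because these estimators are usually validated only against each other,
the package ships a first-class synthetic-data module that generates
ground-truth inputs for every stage (Brownian single-file channels with
known D_n and a crossing log, Boltzmann-sampled occupancies under a known
G(z), pseudo-atom walls with analytic radius profiles, planted contact
interfaces, harmonic mode fluctuations), so the whole pipeline is
verifiable without running molecular dynamics.

## Worked example

Estimate the osmotic permeability of twenty synthetic single-file
channels with a planted D_n = 1.0 ns⁻¹ (200 ns each, frames every
10 ps):

```bash
python analysis/02_osmotic_permeability.py
```

prints, per seed, the fitted D_n and p_f and ends with

```
mean D_n = 0.954 /ns (planted 1.0), mean p_f = 2.85 x 1e-14 cm^3/s (expected 2.99)
```

i.e. the MSD-window estimator recovers the planted collective diffusion
constant to ~5% (slightly low because waters crossing the pore boundary
mid-step lose their contribution), and p_f follows as v_w·D_n.  The
other drivers follow the same pattern — each generates its ground truth,
runs one analysis stage, prints what it found and writes a table under
`results/`:

| driver | what it shows |
| --- | --- |
| `01_count_permeation_events.py` | event counts equal the generator's crossing log exactly |
| `03_pmf_profiles.py` | a 5 kJ/mol Gaussian barrier recovered to 0.07 kJ/mol; merged-monomer averaging |
| `04_pore_radius_profiles.py` | hourglass waist (1.80 Å at z = +10) found exactly; temporal widening map |
| `05_interface_contacts.py` | the planted Ile-93 contact hub isolated by the difference map |
| `06_essential_dynamics.py` | mode 1 carries 64% and the top 10 modes 99% of the fluctuation |
| `07_group_comparison.py` | activated monomers 172 ± 7 vs autoinhibited 11 ± 2 events, Mann–Whitney p = 0.0023 |
| `08_paralog_alignment.py` | PIP1;2/PIP2;5 stand-ins: 66.1% identity, 74.7% similarity; Ala-103 ↔ Ile-93 |

A `chanflux` console script exposes the same stages for file-based
trajectories (`chanflux permeation --top sys.pdb --traj sys.xtc --config
channel.yaml --out events.csv`, likewise `pf`, `pmf`, `pore`,
`contacts`, `ed`, `align`, `compare`, `synth`, and `run config.yaml` for
an end-to-end configured pipeline).

Note on sequences: `data/*_synthetic.fasta` are labelled synthetic
stand-in reconstructions of the two maize PIP paralog sequences, shipped
so the alignment stage runs offline; they are not the database entries.

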