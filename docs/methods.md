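# Methods

This note records the models, conventions and numerical choices behind
each analysis stage, what the synthetic generators do and do not
emulate, and the known limitations.

## Channel coordinate system

All stages share one geometry: a unit axis (default the global z axis,
i.e. the membrane normal of a bilayer simulation), an origin placed at
the channel's NPA-motif region so that z = 0 is the channel midpoint and
the ar/R selectivity filter sits near +10 Å, boundary planes `z_lower`
and `z_upper`, and a lateral cutoff around the axis.  A water —
represented by its oxygen — is *inside* the channel when
`z_lower ≤ z ≤ z_upper` (closed interval; ties are measure-zero in float
data but the convention is fixed for reproducibility) and its distance
from the axis is at most the lateral cutoff.

Defaults: `z_lower = −15 Å`, `z_upper = +15 Å`, `lateral_cutoff = 6 Å`.
These span the NPA through the ar/R constriction with vestibule margin
in a typical aquaporin monomer; all are configurable and the pore length
L used by the collective coordinate defaults to `z_upper − z_lower`.
The origin is the frame-averaged centroid of user-chosen anchor atoms;
`axis_mode="principal_axis"` (leading principal axis of the pooled
anchor coordinates, sign fixed toward +z) supports tilted synthetic
channels, and coincident or collinear anchors are rejected as degenerate.

## Permeation events

Each water's per-frame region (`below`, `inside`, `above`,
`outside_lateral`) feeds a finite-state machine that records an *up*
event on the history below → inside⁺ → above and a *down* event on the
mirror image.  Retreats record nothing; a lateral exit inside the slab
resets the machine to the side matching sign(z), so waters bypassing the
pore mouth are never credited with a crossing.  Multiple events per
water are allowed and the total is the sum of both directions (the
direction split is retained as extra output).  The machine is path-based:
refining the frame rate of a fixed continuous path does not change the
count as long as no boundary crossing is skipped between frames.

## Collective-diffusion osmotic permeability

Per frame step, every water inside the channel at both step endpoints
contributes `dz/L` to the increment of the dimensionless collective
coordinate n(t) (n(0) = 0).  Requiring both endpoints inside is what
makes the estimator well-defined on discrete frames; its cost is a small
downward bias (≈ 5% at the default generator conditions) because
boundary-crossing steps lose their partial contribution.

D_n is estimated Einstein-style: the series is cut into contiguous
200 ps windows, `MSD(τ)` is averaged over windows for lags from one
frame to half the window (the short-lag regime is linear, long lags are
noisy), and a least-squares line through the origin gives
`D_n = slope/2`, clamped at zero (with a flag) if the fitted slope is
negative.  At least 5 windows are required.  Then `p_f = v_w·D_n`,
reported in 10⁻¹⁴ cm³/s with `v_w = 2.99 × 10⁻²³ cm³`
(= 18.015 g mol⁻¹ / (0.997 g cm⁻³ · N_A)).  With D_n in ns⁻¹ this makes
`p_f = 2.99·D_n` in those units.

## PMF by Boltzmann inversion

`G(z) = −k_B T ln⟨n(z)⟩` per axial bin (default width 0.5 Å tiling the
slab; snapshots every 10 ps), with `k_B T = 2.577 kJ/mol` at the 310 K
simulation temperature.  Zero-occupancy bins are *undefined* (NaN), not
+∞ — honest uncertainty and finite plots.  The displayed profile is
shifted so its defined minimum is zero; only differences are meaningful,
and barrier heights are offset-free.  Profiles over equivalent monomers
are computed by pooling occupancies frame-weighted and inverting once
(merge-then-invert), which equals concatenating the trajectories —
averaging per-monomer PMFs would instead take a geometric mean of
occupancies and overstate barriers of mixed active/blocked groups.

## Pore radius

The radius at axial position z is the maximal clearance
`max_p min_i (|p − a_i| − vdw_i)` over centres p constrained to the
plane at z (full 3D distances to wall atoms within 15 Å of the plane;
protein heavy atoms by default).  Radii may be negative (occluded
slice).  The search combines simulated annealing (initial step 1 Å,
cooling ×0.9, 10 proposals per level, temperature tied to the step,
stop below 0.01 Å) from the previous slice's centre plus 3 random
restarts, with a Nelder–Mead polish; centres are constrained within
2× the lateral cutoff of the axis.  A dense-grid reference
(`grid_search_radius_at_z`, default 0.02 Å resolution over the same
disk) provides the exactness oracle.  Van der Waals radii are
Bondi-style (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 Å),
overridable per atom.

Temporal profiles average per-snapshot radii (snapshots every 10 ps) in
2 ns time bins, optionally pooled over several monomers; empty cells are
NaN.  Slices are plane-constrained along a fixed axis — a curved 3D
centreline is not propagated — so on steeply varying walls the slice
radius can undercut the wall profile (the sphere is clipped by narrower
rings above the plane); locally flat features such as a constriction
waist are recovered exactly.

## Interface contacts

Two heavy atoms of different monomers are in contact when within 4.0 Å;
an atom pair is *persistent* when in contact in at least 70% of frames
(the criterion is applied per atom pair).  Persistent atom pairs are
aggregated to residue pairs and normalised by the map's maximum
persistent-pair count, giving frequencies in [0, 1].  Difference maps
subtract frequencies cellwise on the union of residue pairs after an
optional residue relabelling (e.g. the paralog alignment position map);
unmappable residues raise an error naming the offenders.  The kd-tree
neighbour search is exact (verified against O(n²) enumeration).
Periodic images are ignored: intra-tetramer interfaces never wrap the
box.  Raising the cutoff or lowering the fraction can only add
persistent contacts (monotonicity).

## Essential dynamics

Frames are rigid-body superposed (Kabsch) onto frame 1 and then onto the
resulting mean (two passes), removing the 6 rigid degrees of freedom;
fitting is idempotent.  The covariance of the 3N fitted coordinates
(unit weights; mass weighting off, Cα selections recommended) is
diagonalised; eigenvalues in Å² sum to the total mean-square
fluctuation.  Trajectories of equivalent monomers may be concatenated
before the covariance.  The cumulative fraction of the first k modes and
extreme structures along a mode (actual extreme frames, or mean ± qσ
reconstructions) support the usual few-slow-modes interpretation.  The
superposition frame is arbitrary up to a global rotation;
`align_modes_to_reference` re-expresses a mode set in another frame for
cross-system or truth comparisons.

## Group statistics

Per-monomer metrics are summarised as mean ± sample SD (n−1 denominator,
0 for a single value).  Groups are compared two-sided with
Mann–Whitney U, reported as `U = min(U1, U2)` with ties counting ½.  The
exact null (full enumeration, via the standard library routine) is used
for tie-free samples with n₁, n₂ ≤ 12; otherwise a normal approximation
with tie-corrected variance and continuity correction, with p = 1 when
the variance degenerates (all values tied).

## Sequence comparison

Global Needleman–Wunsch alignment under affine gaps: BLOSUM62, gap open
10.0 (charged to a gap's first position), extension 0.5, end gaps
penalised by default (configurable; the EMBOSS `-endweight false`
behaviour is one flag away), X scored 0 against everything.  Identity%
counts identical columns over the full alignment length (gap columns in
the denominator); similarity% additionally counts columns with a
positive substitution score.  Residue numbering is 1-based throughout;
the alignment's position map translates residue numbers between
paralogs for the contact difference maps.  Tie-breaking among co-optimal
alignments follows the aligner's deterministic traceback order; scores
are convention-independent and the statistics of co-optimal alignments
agree to well under a percentage point on realistic protein pairs.

## Synthetic generators: what they emulate, and what they do not

All generators take an explicit integer seed and are bitwise
reproducible; every truth record suffices to score its pipeline stage
without re-deriving ground truth.  They provide *statistical*, not
physical, fidelity — no force fields, no water–protein energetics, no
membrane.

* **Single-file channel** — waters diffuse 1D along the axis (fixed
  small lateral offsets) over the slab plus 10 Å vestibule buffers, with
  periodic recycling at the outer edges so crossings occur at a steady
  rate (a reflecting wall would starve the event counter).  The
  per-water step variance is set from the uniform steady state so the
  collective coordinate diffuses with the requested D_n:
  `D_w = D_n L² / ⟨N_inside⟩`.  The generator logs complete crossings
  with its own bookkeeping as it simulates, giving an independent event
  ledger.  Defaults (100 waters, 10 ps frames, D_n = 1 ns⁻¹) produce
  step σ ≈ 0.55 Å, far below the slab and buffer widths, so no crossing
  is ever skipped between frames.  Real channels add single-file
  correlations and lateral structure that this generator deliberately
  omits; passing tests show estimator correctness, not force-field
  realism.
* **Planted crossings** — deterministic piecewise-linear paths with
  exactly known up/down/retreat counts, for boundary-exact FSM tests.
* **Boltzmann axial occupancy** — inverse-CDF sampling of
  exp(−G(z)/k_BT) on a 4001-point grid.
* **Pore walls** — rings of pseudo-atoms every 0.5 Å whose inner van der
  Waals surface realises the requested radius profile exactly at the
  ring planes, backed by two further concentric shells standing in for
  protein bulk (without them the inscribed-sphere search can escape
  radially through the wall, which real protein packing forbids).
* **Interface toy** — planted atom pairs at 3.5 Å for an exact number of
  frames (8 Å otherwise), laterally separated so no accidental contacts
  arise; with 100 frames the 69/70/71-frame boundary cases are exact.
* **Harmonic modes** — frames = mean + Σ a_k v_k with Gaussian
  amplitudes of prescribed variance and orthonormal mode vectors drawn
  in the orthogonal complement of the mean structure's 6 rigid-body
  directions (superposition removes that subspace, so modes with rigid
  components would be unrecoverable by construction); optional random
  rigid motion per frame exercises the superposition step.

## Problem sizes used in tests and the acceptance script

Recovery checks run at the scale where their statistics are meaningful
on a single CPU in seconds to a couple of minutes: 10⁴–2×10⁴ frames and
100 waters for permeation/D_n (20 seeds for the D_n Monte Carlo), 10⁶
samples for PMF recovery, 10⁴ frames for mode recovery, dense-grid
oracles at 0.02 Å on ≤ 50-atom slices.  Published per-monomer transport
numbers from multi-hundred-ns membrane-protein MD are not reproduced
here — they require the original trajectories; the pipeline's
correctness is established against synthetic ground truth instead.

## Known limitations

* The pore profiler does not follow a curved centreline (plane-
  constrained slices only) and does not reproduce any particular HOLE
  radius table or annealing schedule; agreement is established against
  the analytic/grid oracles instead.
* The contact stage offers no energetic or hydrogen-bond criteria, and
  its residue normalisation (max persistent-pair count) is one of
  several reasonable conventions; it is recorded with the output.
* The permeability estimator assumes equilibrium (no pressure or osmotic
  gradient) and regular frame spacing.
* The shipped paralog FASTA files are synthetic stand-in reconstructions
  (so the sequence stage runs offline) and are labelled as such; analyses
  of the real paralogs should substitute the database entries.
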