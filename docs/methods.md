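# Methods

## Scope and model

piezokit quantifies two complementary observables of mechanosensitive-channel
function. On the structural side, PIEZO1 bends the surrounding bilayer into
an inward-facing dome; given phosphate-marker bead coordinates from a
coarse-grained trajectory, the package separates the two leaflets, measures
the dome depth of each, and maps the membrane surface on a 2D grid. On the
functional side, stretch-activated currents recorded from membrane patches
are summarized by their activation/inactivation kinetics, single-channel
amplitude structure, and pressure sensitivity. Both pipelines are validated
against synthetic data whose generating parameters are known exactly.

## Leaflet assignment

Leaflets are recovered from geometry alone. The cutoff graph joins phosphate
pairs at 3D Euclidean distance ≤ cutoff; the network grown from a seed
particle by breadth-first search is exactly the seed's connected component
(iterated absorption of everything within the cutoff of the growing group is
transitive growth, not one-shot distance to the seed). Choices the method
leaves open were fixed as follows:

- **Seed**: the particle with maximum z, deterministically; its component is
  labelled "upper". Any seed inside the same component yields the same
  partition, so the choice only fixes labels and reproducibility.
- **Cutoff**: 2.0 nm by default — below the leaflet separation of a normal
  bilayer but well above the in-leaflet phosphate spacing (< 1 nm), so each
  leaflet is connected and the two are not.
- **Periodicity**: minimum-image convention in x and y only. Wrapping z
  could short-circuit the inter-leaflet gap through the periodic image, so z
  is treated as open.
- **Validation**: the complementary pass re-grows from the putative other
  leaflet (its lowest-z particle) and must reproduce it exactly. Outcomes
  with ≠ 2 components — merged leaflets, stray particles bridging the gap,
  flip-flopped lipids — are flagged degenerate rather than returned
  silently, so batch analyses can skip those frames instead of silently
  corrupting depth statistics.

Correctness is checked against an independent brute-force union-find oracle
on hundreds of random configurations.

## Dome depth

For one leaflet with phosphate z-values `z_i`:
`surface_level = mean{ z_i : z_i ≥ P90 }` with the 90th percentile computed
by linear interpolation, `bottom = min z_i`, `depth = surface − bottom`.
The percentile threshold is inclusive (≥), so the surface set is never empty
even when the top values tie. Averaging the top decile suppresses random
surface fluctuation; the single minimum is used for the bottom because in
real trajectories it is anchored to the protein and fluctuates little.

**Known bias under noise.** On synthetic fixtures where *every* particle
carries independent z-noise, both terms are biased by extreme-value
statistics: the top-decile mean selects upward noise (≈ +1.7 sd of the
noise on a flat leaflet) and the minimum selects downward noise (the
expected minimum of n = 2000 normal draws is ≈ −3.5 sd). With the default
0.1 nm noise and 2000 beads per leaflet a perfectly flat bilayer therefore
reads ≈ 0.5 nm deep, and estimates across dome amplitudes 0–8 nm regress on
truth with slope ≈ 0.96 and intercept ≈ +0.4 nm. This is a property of the
estimator itself, not of its implementation; it is smaller in real
trajectories because the dome bottom is protein-anchored rather than
free-floating noise. The parameter-recovery test asserts a ±0.05 slope band
and a ±0.3 nm intercept band; the intercept check documents this bias by
failing, and the numbers above are what the acceptance script measures.

## Height maps

Per frame, phosphate x/y positions are binned on a common grid (75 bins per
axis by default) fixed from the first frame's box (or particle extent), and
the mean z per occupied bin is stored; the final map averages each bin over
the frames in which it was occupied, with `frames_counted` recording
coverage. Bins empty in every frame are flagged missing and excluded from
summaries — no interpolation. On the noise-free 6 nm dome fixture the map's
relief (max − min bin) reproduces the amplitude within the smoothing of
~0.5 nm bins, with the minimum at the dome-center bin.

## Rigid-body fitting

Frames are superposed onto a reference structure by Kabsch superposition
(scipy's `Rotation.align_vectors`) of a selected particle subset (e.g.
protein backbone beads), and the optimal rotation + translation is applied
to all particles, expressing the membrane in the protein frame. Selections
of fewer than three or collinear particles are rejected (the rotation would
be underdetermined).

## Synthetic membranes

The generator places each leaflet on the analytic surface
`z(x,y) = ±separation/2 − A·exp(−r²/2σ²)` (inward Gaussian dome of
amplitude A, width σ, centred in the box), on a jittered square lattice so
in-leaflet connectivity under the 2 nm cutoff is guaranteed (specs implying
a lattice spacing ≥ 2 nm are rejected), plus independent Gaussian z-noise.
Defaults: 2000 beads/leaflet in a 40 × 40 nm box (≈ 0.9 nm spacing — a
realistic phosphate surface density), separation 4 nm, A = 6 nm, σ = 5 nm,
noise 0.1 nm, one frame. Species labels follow the asymmetric
endothelial-like composition (upper leaflet 55% POPC / 5% SM / 20% POPE /
20% cholesterol; lower leaflet POPC/POPE/SM/CHOL/POPS/PIP2 in 50:20:5:20:5:5
proportion, renormalized to sum to one) by deterministic largest-remainder
apportionment, so species counts are exact rather than sampled. A single
integer seed makes regeneration bit-identical.

What the generator does *not* emulate: lipid shape and packing
thermodynamics, protein beads, membrane undulation spectra, or correlated
(non-white) positional noise. Passing tests therefore demonstrate the
correctness of the geometry pipeline, not the realism of any particular
membrane model.

## Patch-current analysis

All amplitudes are deviations from the baseline, the mean current over a
50 ms window before stimulus onset (configurable). Inward current is
negative; the peak is the most negative deviation within the epoch.

- **20% decay time**: first time after the peak at which the deviation
  magnitude falls to 80% of the peak, linearly interpolated between samples;
  explicitly censored (never imputed) when the threshold is not crossed
  within the epoch, as for non-inactivating currents or residual plateaus
  above 80%.
- **Decay rate**: rate constant of `|I|(t) = offset + a·e^(−kt)` fitted to
  the post-peak segment by nonlinear least squares (`scipy.curve_fit`,
  positivity bounds, initial rate from the half-drop time). A fitted
  decaying amplitude below 5% of the peak is reported as "non-decaying"
  (rate absent); fit non-convergence is a flagged absence, never an
  exception. The exponential-plus-offset form was chosen because the decay
  rate lacks a printed operational definition in common figure legends; it
  is standard, recovers generated rates exactly, and handles residual
  plateaus.
- **End/peak ratio**: mean deviation magnitude over a stated end window
  divided by the peak magnitude, quantifying sustained (non-inactivated)
  activity.
- **Amplitude histogram**: all-point histogram on left-closed 0.05 pA bins
  anchored at integer multiples of the bin width. Level amplitudes come
  from a two-component Gaussian mixture fitted to the raw samples
  (scikit-learn, fixed random state); if a one-component fit is preferred
  by BIC, or the second component is degenerate (weight < 2% or separation
  below one bin), a single level is returned. The unitary current is the
  separation of the two means; at −80 mV, 1.95 pA corresponds to
  1000·1.95/80 = 24.375 pS.
- **Pressure response**: per-pressure peak amplitudes normalized to the
  −40 mmHg anchor (per recording, not per group), then fitted with
  `f(P) = 1/(1+exp((P_1/2 − P)/s))` on pressure magnitudes, since the
  applied stimuli are suctions recorded as negative mmHg; `P_1/2` is
  reported as a magnitude. Saturated curves (response range < 0.1) and
  non-convergent fits raise a flagged error carrying the residuals. Because
  the anchor itself sits slightly below full saturation, normalization
  biases noise-free end-to-end recovery by 1–4%; fits to un-normalized
  sigmoid samples are exact to the optimizer tolerance (≪ 1e-6).

## Synthetic patch currents

Kinetics fixtures are simulated at the ensemble mean-current level:
`I(t) = −N·i_u·p_open(P)·a(t)` plus white Gaussian noise, with
`p_open(P) = 1/(1+exp((P_1/2 − |P|)/s))` (defaults P_1/2 = 20 mmHg,
s = 5 mmHg over pressures −5…−40 mmHg), unitary current i_u = 1.95 pA,
0.2 s pulses sampled at 20 kHz with 50 ms pre/post padding. The envelope
`a(t)` rises as `1 − e^(−t/τ_act)` (default τ_act = 5 ms; 0 = instantaneous)
and, when inactivation is enabled, decays from the peak as
`r + (1−r)·e^(−k·t')` toward residual fraction r. The inactivation clock
starts when the rise is counted complete (99.9% of asymptote, immediately
when τ_act = 0), which keeps the recorded ground truth closed-form: the
20% decay time is `ln((1−r)/(0.8−r))/k` (censored when r ≥ 0.8), the decay
rate is k, and the end/peak ratio is the envelope value at the pulse end.
Amplitude-histogram fixtures instead use a two-state discrete-time telegraph
process (single channel, stationary open probability and ~5 ms mean open
dwell) because that analysis needs level structure, not ensemble kinetics.
Noise is white and Gaussian; acquisition-chain filtering (2 kHz low-pass)
is not re-applied — traces are taken as already filtered. Simulated
single-channel gating is not Markov-state realistic and voltage dependence
is not modelled.

## Residue-range accounting

Ranges are 1-based and inclusive on both ends (a single residue r is
(r, r)); overlap is rejected at construction. Coverage percentages are
rounded half-up to one decimal. Fragment derivation subtracts excluded
ranges from a chain span and returns the maximal contiguous remainders; the
invariant `count(span) = count(fragments) + count(excluded)` is property-
tested. Applied to the mouse PIEZO1 homology-model bookkeeping (span
577–2547, the four unresolved regions, the eight rebuilt loop ranges) it
reproduces 58 missing residues, 2.3% of the 2547-residue chain, and the
five modeled fragments.

## Problem sizes and determinism

Synthetic fixtures use 2000 beads/leaflet (membrane), 200 random instances
of n ≤ 60 particles (oracle comparison), 4 frames per amplitude for the
recovery regression, 0.3 s traces at 20 kHz (kinetics) and 1 s telegraph
traces (histograms), and 100 replicates for the Boltzmann recovery
simulation — sizes at which every quantity is statistically stable while
the whole suite runs in seconds. All stochastic tests and the acceptance
script are seeded; the generators are bit-reproducible for a fixed seed.

## Known limitations

- The dome-depth estimator's noise bias (above) means absolute depths on
  fully noisy synthetic surfaces run ~0.2–0.5 nm high; comparisons between
  conditions at equal noise are unaffected.
- Leaflet assignment assumes a single bilayer patch; vesicles, stacked
  bilayers, or curvature so extreme that the 3D gap between leaflets falls
  below the cutoff will be flagged degenerate rather than resolved.
- Only orthorhombic boxes and GRO / multi-model PDB inputs are supported;
  binary trajectory formats are out of scope.
- Electrophysiology metrics are descriptive per-trace quantities; group
  statistics, leak subtraction and dwell-time idealization are out of
  scope.
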