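# Methods

This note documents the models implemented in `mycosole`, the choices made
where the underlying methods description was open, and what the synthetic
data generators do and do not emulate.

## Conductive templates

A mycelium network colonising an insole is represented as a binary grid
("conductive matrix"): node `(i, j)` participates in the dynamics iff it is
marked conductive. Three sources are supported:

1. **Thresholded colony images.** A pixel is conductive iff
   `r > 170`, `g > 170` and `b < 200` (strict inequalities; thresholds
   configurable). The rule selects light-green mycelium strands against a
   dark background. A separate nearest-neighbour resize step
   (`resize_nearest`) projects an image onto a differently sized node grid.
2. **Morphological dilation** with a 3×3 square structuring element
   thickens the thresholded strands so that discrete excitation waves can
   propagate along them (1 iteration by default; a 1-node-wide filament
   becomes 3 nodes wide).
3. **Synthetic hyphal growth.** Because no reference colony image ships
   with the package, `generate_mycelium` grows a network inside a
   foot-shaped mask: correlated random walks (Gaussian turning noise,
   sd 0.2 rad/step) start from 6 inoculation points spaced along the
   insole's long axis, branch with probability 0.01/step at ±π/4 relative
   heading (capped at 100 walkers), die at the mask boundary, and are
   finally dilated. With the default parameters on the canonical 364×985
   grid the largest 8-connected component holds ≥ 95% of conductive nodes
   across seeds, and the conductive fraction is ≈ 0.1–0.3 of the grid.
   The model reproduces the *connectivity* and strand-like geometry of a
   colonised insole, not the anastomosis statistics, strand-width
   distribution or growth kinetics of real *P. ostreatus* mycelium.

The insole mask itself is the union of three axis-aligned ellipses (heel
lobe, toe lobe, connecting waist), occupying ≈ 0.59 of the grid — within
the 0.4–0.7 band for any admissible dimensions — and connected by
construction. Grid indexing is 0-based row-major; connectivity uses
8-adjacency (matching the Moore neighbourhood used by the electrodes),
while diffusion acts through 4-neighbours only.

## Excitation dynamics

The two-variable FitzHugh–Nagumo system is integrated on the conductive
subset:

    du/dt = c1·u(u − a)(1 − u) − c2·u·v + I + D_u ∇²u
    dv/dt = b·(u − v)

with explicit Euler stepping (`u ← u + Δt·[...]`, synchronous, pre-step
fields everywhere), a five-node Laplacian, and no-flux boundaries realised
by mirroring the centre value into off-grid or non-conductive neighbours.
Defaults: `a = 0.13` (excitation threshold), `b = 0.013` (recovery rate),
`c1 = 0.26` (cubic coefficient), `c2 ∈ [0.015, 0.05]` (recovery coupling —
the excitability dial), `I = 0`, `Δt = 0.015`, `Δx = 2`, `D_u = 1`.
The cubic `u(u−a)(1−u)` has stable fixed points at `u = 0` and `u = 1`
and an unstable threshold at `u = a`.

Numerical notes:

- The neighbour sum is associated as `(up + down) + (left + right)`, which
  makes every update bitwise invariant under the grid's symmetry group;
  a centre-stimulated run on a uniform grid stays exactly symmetric.
- The production stepper gathers conductive nodes into flat arrays with
  precomputed neighbour indices (mirror realised by self-pointing slots);
  it is verified to ≤ 1e-12 against a naive per-node double loop.
- Any non-finite value aborts with the first offending iteration
  (`IntegrationBlowUpError`). The default parameters sit deep inside the
  explicit-stability regime (`D_u·Δt/Δx² = 0.00375`).

### The calibrated-conductance preset

With the defaults above, planar fronts travel at
`Δt·sqrt(c1·D_u/2)·(1−2a)/Δx ≈ 0.002` nodes per iteration — excitation
would need ~5·10⁵ iterations to cross a ~1000-node network. The working
regime for insole-scale simulations of this kind has waves spanning such
a network within 50–60 K iterations, i.e. ~0.016 nodes/iteration, which
is exactly what the same stencil yields when the Laplacian acts once per
iteration, i.e. a per-step transfer coefficient `D_u·Δt/Δx² = 1/4`.
`FHNParameters.calibrated()` therefore sets `D_u = 1/Δt` (≈ 66.7)
and is used for all insole-scale experiments; the package measures a
strand front speed of ≈ 0.016 nodes/iteration in this regime
(`front_speed_nodes_per_iteration` in the acceptance output). The preset
sits exactly at the explicit-stability boundary; the reaction term's decay
at rest damps the marginal chequerboard mode in all regimes exercised
here, but runs far from the defaults should re-check stability.

### Excitability of the two c2 endpoints

Measured behaviour under the implemented kinetics (both diffusion
regimes):

- The medium is **bistable**: behind a front, `v` relaxes towards `u` and
  the trajectory settles on a stable excited state (`u ≈ 0.93` for
  `c2 = 0.015`, `u ≈ 0.77` for `c2 = 0.05`) rather than recovering to
  rest. Electrode potentials still spike transiently at front arrival
  because `p ∝ u − v → 0` as `v` catches up.
- **Smaller `c2` is the more excitable endpoint**: on a 7-node-wide
  strand, a radius-5 stimulus launches a travelling front at `c2 = 0.015`
  but dies at `c2 = 0.05`; with larger stimuli both endpoints propagate.
  The package therefore records `c2 = 0.015` as the excitable endpoint.
  (Nullcline analysis agrees: `c2` scales the only negative feedback,
  `−c2·u·v`.)
- **Small stimuli do not nucleate on uniform 2-D grids.** A disc of
  radius 1.8 nodes (9 nodes) is below the critical nucleus for every
  parameter combination tested — curvature shrinks it faster than the
  reaction grows it — so the uniform-grid endpoint scan reports zero
  spanning endpoints; the corresponding acceptance check fails and is
  kept as an honest negative result. On quasi-1-D strand networks the
  same kinetics propagate readily from modest stimuli.

### Stimulation

Pressure at an insole locus is imitated by setting `u = 1` on conductive
nodes within a disc around the corresponding electrode (`E1` toe, `E2`
heel), at a scheduled iteration. Insole-scale runs use a radius of
15 nodes — the smallest round footprint that reliably launches waves on
3-node-wide dilated strands in the calibrated regime (the excited strand
segment must exceed the ≈ 8-node front width). The radius, value and
schedule are all configurable.

## Virtual electrodes and read-outs

- **Potential**: `p_x = Σ_{y: |x−y|<2} (u_y − v_y)` over the 3×3 Moore
  neighbourhood of the electrode node (strict Euclidean inequality keeps
  the distance-2 orthogonal nodes out). Only conductive nodes contribute.
  A `summand="centre"` flag reproduces the literal centre-field reading
  `(u_x − v_x)` per contributing neighbour for comparison.
- **Activity**: number of conductive nodes with `u > 0.1` (strict).
- **Coverage**: per-node count of recorded iterations with `u > 0.1`,
  normalised by the grid-wide maximum (all-zero maps stay all-zero).
- **Snapshots**: binary frames of `u > 0.04` every 100 iterations,
  exportable as numbered PNGs.
- The default 16-electrode layout spaces electrodes along the insole's
  medial axis, `E1` in the toe lobe and `E2` in the heel lobe; with
  `snap_to=grid` each electrode is moved to its nearest conductive node,
  since physical electrodes contact the mycelium.

## Spikes and Boolean gates

Spikes are local maxima with topographic prominence ≥ threshold
(window-unbounded, via `scipy.signal.find_peaks`); an optional amplitude
cap (measured on prominence) discards large events. Spike times are apex
times.

Gate extraction compares the spike trains recorded under the three
stimulation scenarios `(x, y) ∈ {(0,1), (1,0), (1,1)}` (`x` ≡ excitation
at `E1`, `y` ≡ at `E2`). Pooled spikes are partitioned into events by
single-linkage chaining with the separation gap (10³ iterations); gaps
larger than the simultaneity window (2·10²) but within the separation gap
are ambiguous and resolved into the earlier event (logged). Each event's
presence triple `(s01, s10, s11)` is the truth table of a Boolean function
of `(x, y)` restricted to the three tested inputs; the resulting 8-way
lookup (CONST-FALSE, AND, x-AND-NOT-y, SELECT-x, NOT-x-AND-y, SELECT-y,
XOR, OR) is verified against brute-force enumeration of all 16 Boolean
functions. On the synthetic template the census mixes SELECT gates (where
the single-input and both-input arrivals coincide within the simultaneity
window) with single-scenario events (x-AND-NOT-y, NOT-x-AND-y) where the
arrival times from the two stimulation sites differ by more than the
separation gap — the per-electrode composition is what discriminates the
stimulation geometry.

## Experimental-recording pipeline and its synthetic stand-in

The analysis pipeline ingests delimited-text logger exports (1 sample/s,
±156 mV acquisition range; timestamps rounded to the second, duplicates
averaged, gaps interpolated and flagged, out-of-range samples clipped and
flagged) and computes, per differential channel (`Ch 1-2` … `Ch 15-16`):

- **Windowed spike census** over a load schedule (`no-load`, `even`,
  `heel-bias`, `toe-bias`; half-open `[start, end)` windows, boundary
  spikes belong to the earlier window), at 0.03 mV prominence with the
  < 0.1 mV amplitude cap;
- **Inter-spike-interval histograms** pooled per condition on a common
  bin axis (default 60 s bins);
- **Amplitude summaries** (mean/sd/n of prominence — robust to baseline
  drift) per channel × condition, plus the signed `even − no-load` mean
  difference per channel.

The synthetic generator plants, per schedule window, an exact number of
biphasic spikes (9-sample half-sine lobe, 5% negative after-lobe) at
uniform random times with ≥ 10×-width spacing and 2×-width edge margins,
amplitudes from clipped normals per condition, on a slow sinusoidal
baseline (0.004 mV, 1 h period, per-channel phase) plus **bounded uniform
noise** with the requested standard deviation (default 0.005 mV).

Defaults encode the study conditions: ≈ 2 spikes per 30-min window
unloaded vs ≈ 8 under even load (6 under biased load), and a 30% lower
spike amplitude under even load (0.042 vs 0.060 mV mean). The
before/during/after schedule is three 30-min windows.

Why bounded noise: the detector calibration (0.03 mV prominence over
0.005 mV noise) is only meaningful if noise-only fluctuations cannot reach
the threshold. For any unbounded (e.g. Gaussian) noise the extreme
prominence in a 1800-sample window concentrates near 5–6σ ≈ 0.03 mV, so
false positives are guaranteed at scale. Logger samples are averages of up
to ten ADC readings and their residual fluctuations are band-limited;
modelling them as uniform within ±√3·sd keeps every moment matched to the
nominal sd while bounding noise-only prominence at
`2√3·sd + 2·drift ≈ 0.025 mV < 0.03 mV` deterministically. What passing
recovery tests show, therefore, is that the pipeline is exact whenever
spikes clear the threshold and noise cannot — they do not certify
behaviour on recordings whose noise excursions overlap the spike scale.
Amplitude ceilings (0.068 mV) are likewise chosen so the worst-case
prominence (amplitude + noise band + drift swing + a neighbour's negative
lobe) stays below the 0.1 mV cap.

The generator does not emulate: electrode drift steps, mains interference,
bursting or non-stationary spike rates, waveform asymmetries between
channels, or the slow humidity-driven trends of living insoles. Conclusions
about real recordings should rest on the pipeline, not on the generator.

## Problem sizes used by the test suite and acceptance script

Uniform-grid experiments run on 50×50–140×220 grids for 2–4 K iterations;
the endpoint scan on 100×100 for up to 60 K (early exit on a dead medium);
template spanning and the three-scenario gate census on a half-scale
(182×492) synthetic insole for 10⁵ iterations each; recording-pipeline
replicates use 100 seeds of 90-min, 8-channel recordings. With these sizes
the full pytest suite runs in ~1.5 min and the acceptance script in
~3 min on one CPU.

## Known limitations

- The bistable kinetics mean no spiral waves or repeated wave trains arise
  on homogeneous substrates; oscillatory activity would require either a
  different coupling form or heterogeneity not modelled here.
- The uniform-grid endpoint scan is kept as a failing check (see above):
  the canonical 9-node stimulus cannot nucleate on a uniform 2-D medium
  under any reading of the printed constants.
- Electrode coordinates of the original 16-electrode configuration are not
  tabulated anywhere; the default layout is a geometric construction, and
  no waveform-level reproduction of the original electrode figures is
  attempted.
- `read_logger_export` trusts the header row and first-column timestamps;
  multi-file sessions and vendor-specific metadata blocks are out of scope.
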