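# Methods

`actomyosim` couples a simplified stochastic mechanochemical model of a
cortical actomyosin patch to a quantification suite for the spatial
organization of actin filaments and myosin motors.  This note records the
model, its assumptions, the defaults and why they were chosen, and what the
synthetic tests do and do not establish.

## The model

### Geometry

The simulation box is a thin cortical patch, `[0, Lx] x [0, Ly] x [0, Lz]`
with defaults 2000 x 2000 x 200 nm, subdivided conceptually into 200-nm
cubic compartments.  Confinement is a hard wall (one-sided quadratic
penalty); there is no periodicity.  Coordinates are nm, forces pN, times s.

Actin filaments are bead chains with 108-nm equilibrium segments; the last
bead is the barbed (plus) end, and every polarity-dependent rule reads that
convention.  Binding sites are spaced `d_total = 27 nm` along the chain
(four per segment).  Myosin minifilaments are bipolar two-headed agents with
a sampled head count `N_t` per species range (resampled at each binding, to
model minifilament-to-minifilament variability); crosslinkers are identical
agents without walking, with an alpha-actinin-like reaction range
(30-40 nm), stiffness 8 pN/nm, and on/off rates 0.3/s.

### Motor kinetics

Per-head parameters follow the non-muscle myosin IIA minifilament baseline:
step size `d_step = 6 nm`, per-head binding rate `k_bind = 0.2/s`, stall
force `F_s = 100 pN`, head count range 15-30, stretching force constant
`K = 2.5 pN/nm`, per-head unbinding force `F_0 = 12.62 pN`, reaction range
175-225 nm.  Derived ensemble rates follow the parallel-cluster-model
picture for non-processive motors:

* duty ratio `rho = k_bind / (k_bind + k_unbind)`, with `k_unbind = 1.8/s`
  by default so the baseline duty ratio is ~0.1;
* unloaded walking rate `k0 = (d_step / d_total) ((1 - rho)/rho) k_bind`.
  Note the algebraic consequence that with a fixed per-head unbinding rate
  this reduces to `(d_step/d_total) k_unbind`; the binding-rate sweeps
  therefore act through attachment flux and residence time, not through
  walking speed;
* loaded walking `k(F) = max{0, k0 (F_s - F)/(F_s + F/alpha)}` with
  `alpha = 0.2` (walking stalls exactly at `F_s`);
* unbinding is a pure catch bond,
  `k_u(F) = k_u0 exp(-F / (N_bound F_0))` with `N_bound = max(1,
  round(rho N_t))` load-sharing heads.

The zero-force minifilament unbinding rate uses the closure

    k_u0 = k_unbind (1 - rho)^(rho * N_ref) / N_t,        N_ref = 20,

i.e. residence time proportional to the head count, with a duty-ratio
factor expressing that a stickier ensemble (more simultaneously bound
heads) releases completely far more rarely.  `N_ref` is a fixed reference
ensemble size rather than the sampled `N_t`, which keeps `k_u0` exactly
proportional to `1/N_t`.  Minifilament attachment occurs at propensity
`k_bind * mean(N_t range)` whenever a pair of binding sites on two distinct
filaments, separated by a distance inside the reaction range, lies within
400 nm of the diffusing motor.

### Dynamics

Chemistry and mechanics alternate on a `dt_chem = 1 s` cadence.

* **Chemistry** is sampled exactly (Gillespie) within each window, with
  mechanical forces frozen at their last relaxed values.  Events: tip
  polymerization/depolymerization at both filament ends (default 0.04/s for
  all four reactions — symmetric segment exchange, i.e. turnover without a
  net treadmill translation, which in a closed 2-um box would walk
  filaments into the walls; the rates are config-exposed), motor and linker
  binding/unbinding, and plus-directed motor stepping by `d_step` per event
  and per endpoint.  A depolymerized segment force-releases anything
  attached to it.  Walking clamps at the plus end.  One refinement to the
  frozen-force rule: a walk event immediately re-evaluates that motor's own
  spring tension on the frozen bead geometry, so a low-stall-force motor
  stalls (and its catch bond tightens) within the window rather than only
  after the next relaxation.
* **Diffusion** of unbound motors/linkers is one Brownian displacement per
  window (`sigma = sqrt(2 D dt)`, `D = 1e5 nm^2/s`, reflecting walls).
  With these defaults a motor mixes over several compartments between
  binding events, which is the well-mixed-compartment limit; explicit
  compartment-hop events would add ~10^2 events/s per motor with no
  behavioral difference at this scale.
* **Mechanics** minimizes the total elastic energy (filament stretching
  10 pN/nm, discrete bending 400 pN nm — a ~10 um persistence length at the
  segment scale — motor/linker Hookean springs with rest length fixed at
  the binding-time separation, soft excluded-volume repulsion below 10 nm
  bead clearance, wall penalty) by monotone Barzilai-Borwein descent with
  Armijo backtracking (numba-compiled), to a 0.1 pN residual-force target
  or an iteration cap.  During a run each window gets a 60-iteration
  budget: successive windows then approach the quasi-static limit the way
  finite-drag overdamped dynamics would (typical post-window residuals are
  ~1 pN, far below motor-scale forces), while the standalone relaxation
  entry point runs with the full cap (5000).  Energy is never allowed to
  increase across a relaxation.
* A bound motor stretched beyond twice the upper reaction range is
  force-released (logged); this is a numerical guard that fires mainly when
  treadmilling carries a filament away from a stalled motor.

Scheduled parameter switches (e.g. the binding-rate switch protocol) are
applied exactly once at their time point by splitting the chemistry window
there.

Runs are reproducible bit-for-bit given the configuration and seed.

## The measures

* **Radius of gyration** `R_g`: RMS distance of all filament beads from
  their geometric centre; time series are normalized by the first frame.
  Decreasing `R_g` indicates contraction.
* **Orientational order** `S`: largest eigenvalue of
  `Q = (3/2)(<r_hat r_hat^T> - I/3)` over filament end-to-end unit vectors;
  0 = isotropic, 1 = perfectly aligned (nematic: antiparallel counts as
  aligned).
* **Radial distribution**: normalized histogram (50 bins, half-open, last
  bin closed) of all pairwise bead distances over `[0, d_max]` with `d_max`
  the full 3-D box diagonal, so the masses sum to exactly 1.  (The planar
  diagonal `2000*sqrt(2)` would exclude a sliver of admissible pair
  distances in the 200-nm-thick box.)
* **Motor localization**: counts of bound motors in cylindrical annuli
  about the domain axis with boundary radii 0, 250, 500, 750, 1000 nm; the
  last annulus is unbounded, so the counts always sum to the bound total.
* **Motor spread** `A_mot`: area of a concave boundary polygon around bound
  motor centres in x-y, over `L^2`.  The boundary is an alpha-shape family
  driven by a shrink factor: Delaunay triangles are peeled in order of
  decreasing circumradius as long as the region stays a single simple
  polygon containing every point; shrink 0 keeps everything (convex hull),
  shrink 1 takes the tightest feasible prefix, and the default 0.5
  interpolates.  Area is therefore non-increasing in the shrink factor by
  construction.  Diffusing motors are excluded: their positions are
  well-mixed placeholders, not organization.
* **Segregation**: for two motor populations, the normalized intersection
  `A_int = |P1 n P2| / |P1 u P2|` of their boundary polygons and the
  centroid distance `D_cent` normalized by the box side `L` (normalizing a
  distance by `L^2` would not be dimensionless).  Degenerate inputs (< 3
  distinct or collinear points) yield flagged-invalid values in batch mode
  rather than exceptions.
* **Ripley's K / H**: `K(r)` on the x-y projection with translation edge
  correction by default (the bare estimator is available), transformed to
  `H(r) = sqrt(K/pi) - r` and summarized as the signed trapezoidal area
  under H on a 100-point grid from 0 to `L/2`.  Positive = clustered,
  ~0 = complete spatial randomness, negative = regular.  Actin enters as a
  seeded 30% per-filament bead subsample; motors as bound-motor centres.
  In trajectory batches the statistic is evaluated every 250 s when the
  span permits, else at every frame.

### Known numerical behavior of the H statistic

At sparse point densities the L-transform is biased slightly negative at
small r (below the nearest-neighbour scale the neighbour counts are mostly
zero, and `E[sqrt(K)] < sqrt(E[K])`).  Measured under CSR on the default
grid: mean signed area ~ -2.0e3 nm^2 at 200 points but ~ -9e1 nm^2 at 1000
points, decaying roughly like 1/n^2 while the replicate noise decays like
1/n.  Pattern-recovery validation therefore uses 1000-point CSR fixtures;
sign-based cluster/regular classification is unaffected at any tested
density (signals are two orders of magnitude above the bias).

## Synthetic fixtures

Generators provide ground-truth structure without any simulation: CSR
(uniform), Thomas cluster (Poisson offspring, Gaussian sigma around uniform
parents; offspring clipped, not reflected, at the walls — a small edge
density loss that the interior-weighted statistics tolerate), jittered
lattices, aligned/isotropic filament fields, inward-polarity asters, and
paired motor clouds whose two populations share one noise draw so that the
centroid separation is exactly the requested offset.  All generators are
deterministic given (spec, seed) and default to the production box.

What passing these tests shows: the measures recover known structure of
point processes and filament fields at production geometry.  What they do
not show: anything about real cortical imaging data (no noise model, no
localization error, no boundary effects beyond the box wall).

## Experiment drivers and problem sizes

Sweeps change one motor parameter at a time; two-motor runs split the same
total motor count equally between two parameter sets; the switch protocol
changes one parameter mid-run (published protocol: binding rate between
0.8/s and 0.4/s, switched 4000 s into 9000 s — the desk preset scales this
shape down).  Aggregation reports per-time mean and sample SD over seeds
(seed = base + run index, recorded per row).  Dominance is summarized by
group medians of the first time the normalized `R_g` leaves the ±5% / ±10%
band, censored runs counted but excluded from medians.

The test-suite trend ensembles use 8 seeds x 600 s simulated at full
baseline composition (2000 x 2000 x 200 nm, 32 motors, 20 filaments, 30
linkers); the acceptance script uses 3 seeds x 400 s.  These durations are
the package's desk scale: the step-size and motor-count effects separate
cleanly from the turnover-driven relaxation of the network within them,
while full reruns stay inexpensive.  The stall-force, binding-rate and
head-count contrasts are intrinsically small in this simplified model
(~0.02-0.03 in final normalized R_g against ~0.08 between-seed noise; see
Limitations), so their ensemble comparisons are near the resolution
limit.  The
paper-scale durations (2000-9000 s) remain available through configuration
and the CLI `--preset paper`.

## Design choices where the design was open

* Minifilament binding propensity (`k_bind * mean heads`) and the
  unbinding closure above: the ensemble kinetics are stated only through
  their qualitative dependences; both closures are the simplest forms with
  the right monotonicities and exact `1/N_t` scaling.
* `d_total = 27 nm` (four sites per 108-nm segment), `alpha = 0.2`,
  `k_unbind = 1.8/s`: named but unvalued constants; chosen for a ~0.1
  baseline duty ratio and a ~0.4/s baseline unloaded walking rate.
* Filament count (20), initial length (540 nm), linker count (30): not
  printed; config-exposed and chosen to give a connected but unjammed
  network at baseline.
* `N_t` is resampled at every binding event rather than fixed per motor
  for the run.
* Eq.-style normalizations: RDF range = 3-D diagonal; centroid distance
  normalized by `L` (both flagged in the module docs).
* Mechanics constants (stretching 10 pN/nm, bending 400 pN nm, excluded
  volume 20 pN/nm below 10 nm, wall 2 pN/nm) are stand-ins at the coarse
  segment scale, not fits.

## Limitations

* Mechanics is energy minimization between chemistry windows, not Brownian
  dynamics: thermal filament fluctuations and viscous time scales are not
  represented; the per-window iteration budget sets an artificial drag.
* Excluded volume acts between beads, not segments, so deeply crossed
  filaments can pass at large bead spacing.
* Binding-site occupancy is not tracked (two motors may bind the same
  site); binding candidates are refreshed once per chemistry window, so a
  motor unbinding mid-window cannot rebind until the next window.
* The simulator is a desk-scale stand-in for full mechanochemical platforms
  (MEDYAN-class): filament force fields, reaction-diffusion compartment
  chemistry and excluded-volume potentials are deliberately simplified, so
  quantitative values (absolute `R_g` levels, absolute crossing times) are
  not comparable — only directions of parameter effects are.
* The binding-rate effect on organization is carried entirely by residence
  time and attachment flux (see the walking-rate note above); it is among
  the weakest of the reproduced trends.
* Which published parameter effects the desk-scale model resolves: the
  step-size family (both contraction and motor spread), the binding-rate
  ordering of final contraction, motor-count contraction, and large-step
  dominance in mixtures reproduce robustly.  The stall-force and head-count
  orderings, binding-rate-pair segregation, and the post-switch drift are
  real but tiny here (at or below ~0.03 in final normalized R_g against
  ~0.08 between-seed scatter) and their sign at any one seed set is not
  meaningful.  Two readouts are structurally out of reach: the boundary
  polygon around 8 motors measures sampling sparsity rather than spread, so
  the motor-count effect on A_mot inverts; and the per-seed "pooled between
  the singles" tuning interval for close parameter pairs is narrower than
  the per-seed scatter at this scale.
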