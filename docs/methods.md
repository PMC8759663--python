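# Methods

## The model

`spotdyn.sim` evolves N point agents on an L×L pixel grid with periodic
boundaries, coupled to a chemoattractant field c(x, t) on the same grid.
Per step of length Δt (Euler–Maruyama for agents, explicit FTCS for the
field, same Δt for both):

1. **Field.** c undergoes 5-point-stencil diffusion (coefficient `D_chem`),
   multiplicative first-order decay `(1 − k·Δt)`, and a deposition of
   `s·Δt` into each agent's containing pixel. Periodic diffusion conserves
   mass, so the per-step balance `total' = total·(1 − kΔt) + N·s·Δt` holds
   exactly and is asserted in the tests. The stability bound
   `D_chem·Δt ≤ 0.25` is enforced at parameter construction; within it the
   scheme also preserves non-negativity.

2. **Motility switch.** Each agent is in one of four phases, cycling
   MOTILE → IMMOTILE_FIXED → IMMOTILE_STOCHASTIC → BLIND → MOTILE.
   A motile agent whose local concentration reaches the threshold `c_star`
   immobilizes; because concentration tracks local cell density, this is a
   density-dependent motility transition. It then waits out a fixed
   refractory interval `t_refractory`, after which it regains motility
   with constant probability `p_reactivate` per step (geometric wait with
   mean `Δt/p_reactivate`), and finally ignores the gradient for a blind
   interval `t_blind` of pure Brownian motion, which lets reactivated
   cells actually escape the high-concentration core. The expected
   immotile episode is `t_refractory + Δt/p_reactivate`; a seeded
   population test checks the realized mean to 5%.

3. **Positions.** Motile agents move by
   `v·Δt + sqrt(2·D_agent·Δt)·ξ` with ξ standard normal per axis and the
   receptor-law drift `v = chi0·∇c/(1 + c/c_half)²` — drift increases with
   the gradient but saturates with concentration, emulating receptor
   occupancy. Blind agents take only the Brownian term; immotile agents do
   not move. Concentrations and gradients are sampled off-lattice by
   central differences on the grid followed by bilinear interpolation
   (grid values live at pixel centers). Finite agent size is a soft
   pairwise repulsion: pairs closer than `r_agent` are pushed apart by
   half the overlap each (applied only to movable agents), implemented
   with a periodic k-d tree. Positions wrap modulo L.

Agents neither divide nor die; the population and its RNG stream are
fixed, so identical `(params, seed)` reproduce runs bit-for-bit (one
uniform and one 2-normal draw are consumed per agent per step regardless
of state, keeping the stream independent of the state mix).

## Control parameters and scales

The model is formulated in internal units (px, time-units, arbitrary
concentration). The full-scale control run uses 100,000 agents on a 384²
grid, Δt = 0.005, t_final = 2000. The motility-switch timescales are
fixed in wall-clock terms — 3 min refractory, 30 min expected stochastic
wait, 15 min blind walk — which the shipped control set realizes with
1 time-unit ≙ 5 minutes: `t_refractory = 0.6`, `p_reactivate = Δt/6`,
`t_blind = 3.0`. The blind interval is sized so a newly mobilized agent
diffuses a distance of order one aggregate diameter
(`sqrt(4·D_agent·t_blind) ≈ 1.9 px ≈ 0.5 mm` at the calibrated scale).

The remaining dynamical constants (`D_agent = 0.3`, `D_chem = 5`,
`s = 1`, `k = 0.2`, `chi0 = 12`, `c_half = 4`, `c_star = 10`,
`r_agent = 0.3`) were chosen by numerical exploration with a single
criterion: the run must form aggregates whose relative size and spacing
resemble the plate experiments (nearest-neighbor spacing a few aggregate
diameters) while motile and immotile populations coexist. Guideposts:
the uniform-state concentration is `c0 = ρ0·s/k ≈ 3.4` for the control
density ρ0 ≈ 0.65 agents/px², so `c_star ≈ 3·c0` immobilizes only in
emergent high-density regions; the attractant screening length
`sqrt(D_chem/k) = 5 px` sets the aggregate spacing scale. These constants
are frozen in `configs/control.toml` and as the `SimParams` defaults;
everything is overridable through the config file.

Physical units are attached afterwards by `calibrate_scales`: the spatial
scale equates the mean segmented aggregate area with a reference area in
mm², and the time scale equates the mean displacement-based speed of
moving agents with a reference speed in mm/hr. Minute-valued switch
parameters can then be re-expressed in time-units with
`minutes_to_time_units` and the run repeated once (simulate → calibrate →
re-express → final run).

## Reduced (desk-scale) runs

Full-scale runs are expensive, so tests and the shipped
`configs/desk.toml` use 10,000 agents on a 128² grid for 10⁴ steps
(t_final = 50). This preserves the control agent density (~0.6/px²) and
all per-unit dynamics, shrinking only the domain and the horizon. At this
scale the model still forms tens of aggregates, retains a persistent
motile fraction (~0.5–0.6 at t = 50, still relaxing toward its
plateau), and produces multiple merging events; the published full-scale
plateau (~40% motile) and merging rate are expected only at control
scale, which the test suite does not run.

## Segmentation and tracking

Aggregates are segmented from agent snapshots by the density rule: for
each pixel, the number of agents within 3 px of the pixel center
(periodic metric, exact point-in-disc counting via a k-d tree — not a
binned convolution); pixels with counts strictly greater than 40 are
aggregate pixels; 8-connected components (merged across the periodic
seam) with fewer than 10 pixels are discarded. Centroids are periodic
(circular) means of member pixel centers; area is the pixel count.

Linking is greedy nearest-neighbor: per frame transition, candidate
(track head, detection) pairs within a distance gate are linked in
ascending distance order, each side used at most once. A track that loses
every in-gate detection to a closer competitor is terminated and recorded
as merging into the winner of its nearest in-gate detection; unmatched
detections seed new tracks. The default gate is 3× the mean
frame-to-frame nearest-centroid displacement. That jitter-scale gate is
right for track continuity but systematically misses coalescence, where
the surviving centroid jumps by roughly one aggregate radius; for merge
analysis `coalescence_gate` therefore adds the mean equivalent radius
`sqrt(area/π)` to the default. Widening the gate much beyond that begins
to chain unrelated neighbors into spurious multi-way merge groups.

Merge classes count partners transitively through survivor chains
(union-find over merge events): 0 partners → non-merger, 1 → two-spot
merger, ≥2 → three-spot merger, so a survivor that later merges again
promotes its whole chain, matching the "merged with two other
aggregates" category. The aggregate-count reduction is
Σ(participants − 1)/n_tracks.

## Point-pattern statistics

**Voronoi neighbor distances.** "All nearest neighbors" of a point are
its Voronoi-adjacent (Delaunay) neighbors. The estimator pools the
distance of every adjacent pair once, including pairs whose cells are
unbounded: on the matched uniform ensemble (100 × 1340 points in a
100×100 mm square) this pooled distribution has mean 3.35 mm and sd
3.00 mm — the long convex-hull edges supply the heavy right tail that
the sd reflects. Excluding unbounded-cell pairs (available via
`exclude_unbounded=True`) shrinks the sd to ≈2.3 mm and is not the
default. Degenerate (collinear) inputs surface a tessellation error with
context.

**Pair correlation.** No periodic wrap (plates are not periodic); edge
bias is handled solely by excluding focal points within `r_max` of any
boundary. For each focal point, distances to all other points are
histogrammed into bins `[n·dr, (n+1)·dr)`; counts are normalized by the
global density ρ = N/L² and the annulus area π(r_out² − r_in²) and
averaged over focal points (implemented as one pooled histogram, which is
algebraically identical). Defaults `dr = 0.1 mm`, `r_max = 20 mm` for
100 mm patterns. Note that within a single pattern the bins co-fluctuate
with the realized interior density (≈2% sd at n = 4000), so tests that
pin g ≈ 1 for uniformity average several patterns.

**Structure factor.** Computed from g(r) by trapezoidal quadrature of the
sine-kernel integral `s(k) = 1 + 2πρ/k ∫₀^rmax (g(r) − 1) sin(kr) dr`,
reproducing the printed analysis formula; the exact 2D isotropic
transform uses a Bessel J₀ kernel and is available via
`kernel="bessel"`. k = 0 is excluded; g ≡ 1 maps to s ≡ 1 identically
under both kernels.

**Null models.** The uniform (binomial) pattern and a hard-sphere
pattern by sequential random insertion with minimum spacing `d_min`
(10⁶ consecutive rejections → explicit saturation error). The
polydisperse variant draws Gaussian radii (CV defaulting to the observed
spot-size CV of 0.3, truncated at zero) and rejects candidates
overlapping the sum of radii; CV = 0 reduces exactly to the monodisperse
generator.

## Trajectory analysis

Speed is total path length over elapsed time (an alternative
mean-frame-speed is a one-line change but not what "average speed" is
taken to mean here). Path directness is path length over net
displacement, ≥ 1 by the triangle inequality, undefined (NaN, excluded)
for closed paths. The MSD uses displacement from each track's first
point, ensemble-averaged at common lags, fit by least squares on log-log
axes over lags up to 50% of the shortest track, ≥ 5 lags; this handles
heterogeneous track lengths without time-averaging within tracks.

Merging kinematics fit the relative distance of a pair,
`d(t) = d0 − v0·t − (a/2)·t²`, by ordinary least squares; the closing
acceleration `a = −2·c₂` is positive for an accelerating approach.
Series with fewer than 20 points are excluded (their dynamics cannot be
pinned down at comparable accuracy). Force-law fits (`A0·e^{−n·d}` or
`A0/dⁿ`) act on accelerations estimated by central second differences of
a 3-point moving average of d(t) — raw second differences amplify frame
noise — and a fit is flagged excluded when the exponent's standard error
reaches 50% of |n| or the optimizer fails; exclusion is a flag, not an
exception. Cohort summaries report class fractions, per-class speed and
directness means, Spearman correlations (merging acceleration vs total
merged area; non-merger speed vs per-frame minimum nearest-neighbor
distance averaged over frames, plain NN, not Voronoi), and a Student
(equal-variance) unpaired t-test of merger vs non-merger speeds, with
Welch available. Degenerate inputs (zero variance, < 2 members) yield
NaNs rather than errors. No multiple-testing correction is applied.

## Synthetic fixtures

Generators in `spotdyn.synth` invert the analyses: `gen_merger_pair`
realizes the constant-acceleration law exactly (plus optional Gaussian
positional noise, truncated strictly before contact, with the analytic
contact time exposed for checking); `gen_scaling_tracks` produces
Brownian (α = 1) or constant-velocity (α = 2) ensembles;
`gen_planted_aggregates` plants uniform discs of agents (centers
separated by > 4 radii) in a sea of free agents; the packing generators
are described above. The central test pattern is the round trip:
analysis(generator(θ)) ≈ θ. What these fixtures do **not** emulate:
segmentation noise from photography, missed detections and gap closing,
drift of the imaging rig, aggregate dissolution, or non-quadratic
approach dynamics — so passing round trips validate the estimators, not
the full measurement chain of a plate experiment.

## Numerical and degenerate-input choices

- Thresholding is strict (`counts > 40`), per the stated rule.
- Segmentation connectivity is 8-connected; the periodic seam is merged
  by union-find before the minimum-area cut.
- Coincident agent pairs in the repulsion step have no defined direction
  and are skipped.
- The quadratic and MSD fits use `numpy.polyfit`; force laws use
  `scipy.optimize.curve_fit` with moment-based starting values.
- KS comparisons use the asymptotic two-sided two-sample statistic.
- Snapshot HDF5 round trips are lossless; the CSV text export carries 9
  significant digits.

## Known limitations

- The drift law and control constants are this package's own choices
  satisfying the stated qualitative criteria; other parameter sets can
  also form aggregates with different merging rates.
- The linker has no gap closing and no global (Hungarian) assignment;
  segmentation flicker near threshold produces short-lived tracks that
  inflate track counts on simulation output. Merge-event detection at
  the coalescence gate is robust to this, but absolute track-count
  fractions from simulations depend on the gate and snapshot cadence.
- Full-scale control runs (100,000 agents, 2000 time-units) are not
  exercised by the test suite; desk-scale runs verify the phenomenology
  qualitatively.
- The sine-kernel structure factor is a faithful implementation of the
  analysis formula, not the exact 2D transform (use the Bessel kernel
  for that).
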