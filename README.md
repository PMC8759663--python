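# spotdyn

Chemotactic bacteria that are uniformly mixed into soft agar can organize
into thousands of millimeter-scale aggregates ("spots"). In
*Enterobacter cloacae* these aggregates do something unusual: after
forming, they migrate over distances of several diameters, and roughly a
third of them merge with a neighbor. `spotdyn` is a toolkit for studying
this phenomenon end to end: an agent-based model that reproduces it, and
the quantification pipeline used to analyze both simulated and
experimental aggregate data.

It is aimed at researchers in bacterial collective behavior / active
matter who want to simulate aggregate formation under a density-dependent
motility switch, or to quantify aggregate patterns and trajectories from
tracking exports.

## The model

N agents perform Brownian motion on a periodic pixel grid with a
chemotactic drift up the gradient of a self-secreted attractant c(x, t),
using receptor-law sensitivity:

    dx = chi0 * ∇c / (1 + c/c_half)^2 * dt + sqrt(2 D_a dt) * ξ

The field obeys secretion–diffusion–decay,

    ∂c/∂t = D_c ∇²c − k c + s Σ_i δ(x − x_i),

integrated by explicit finite differences with the same step. On top of
this Keller–Segel-type core sits a transient, density-dependent motility
switch: an agent whose local concentration exceeds a threshold c* becomes
immotile; it stays fixed for a refractory interval (3 min), then regains
motility with constant probability per step (expected wait 30 min), and
finally performs gradient-blind Brownian motion for 15 min before
resuming chemotaxis. This switch is what lets dense aggregates of
immotile cells coexist with free swimmers, shed cells, migrate, and
merge.

The analysis side implements:

- density-based segmentation of agent snapshots (counts within a 3 px
  radius, threshold > 40, minimum area 10 px) and greedy
  nearest-neighbor track linking with merge-event classification
  (non-merger / two-spot / three-spot);
- spatial statistics of point patterns: pooled Voronoi-neighbor distance
  distributions, the radial pair correlation g(r) with
  boundary-exclusion edge handling, the structure factor
  s(k) = 1 + 2πρ/k ∫ (g−1) sin(kr) dr, and uniform / hard-sphere /
  polydisperse-packing null patterns;
- trajectory metrics: average speed, distance/displacement, the
  anomalous-diffusion exponent from ensemble MSD, relative-distance
  kinematics of merging pairs under a constant-acceleration model,
  exponential/power force-law fits, and cohort statistics (Spearman
  correlations, unpaired t-test).

Synthetic generators with known ground truth (`spotdyn.synth`) back every
analysis stage, so the whole chain is testable without external data.

## Worked example

Fit the merging kinematics of a synthetic aggregate pair generated with
known ground truth (closing acceleration 0.004 mm/hr², initial closing
speed 0.05 mm/hr, initial separation 3 mm, positional noise 0.01 mm at a
15-minute cadence), then compare a uniform random point pattern ensemble
against the published aggregate-pattern statistics:

```python
import numpy as np
from spotdyn import synth, kinematics as kin, spatial

rng = np.random.default_rng(0)
a, b = synth.gen_merger_pair(a=0.004, v0=0.05, d0=3.0, noise_sd=0.01,
                             n_points=40, dt=0.25, rng=rng)
t, d = kin.relative_distance(a, b)
fit = kin.merging_kinematics(t, d)
print(f"closing acceleration: {fit.acceleration:.5f} mm/hr^2")
print(f"initial closing speed: {fit.v0:.4f} mm/hr")
print(f"initial separation:   {fit.d0:.3f} mm")
print(f"rms residual:         {fit.rms_residual:.4f} mm")

pooled = np.concatenate([
    spatial.voronoi_neighbor_distances(spatial.random_pattern(1340, 100.0, rng))
    for _ in range(100)
])
print(f"pooled Voronoi neighbor distances: mean {pooled.mean():.2f} mm, "
      f"sd {pooled.std(ddof=1):.2f} mm")
```

Output:

```
closing acceleration: 0.00345 mm/hr^2
initial closing speed: 0.0514 mm/hr
initial separation:   3.001 mm
rms residual:         0.0124 mm
pooled Voronoi neighbor distances: mean 3.36 mm, sd 3.03 mm
```

The quadratic fit recovers the planted parameters to within the noise
(the acceleration estimate sits inside two standard errors of 0.004),
and the uniform ensemble of 1340 points per 100×100 mm reproduces the
reference values for a matched random pattern (mean 3.35 mm,
sd 3.00 mm).

A simulation is one command:

```
spotdyn simulate --config configs/desk.toml --seed 1 --out run.h5
spotdyn segment --in run.h5 --out detections.csv
spotdyn track --in detections.csv --out tracks.csv --events-out merges.csv
spotdyn kinematics --tracks tracks.csv --events merges.csv --out-prefix run
```

`configs/control.toml` holds the full-scale control parameter set
(100,000 agents, 384² grid, 2000 time-units); `configs/desk.toml` is the
reduced set (10,000 agents, 128² grid, 10⁴ steps) with identical agent
density and per-unit dynamics. `spotdyn sweep` varies one parameter
across runs and summarizes the resulting phenomenology; `spotdyn
spatial` and `spotdyn synth` expose the pattern statistics and
generators. See `docs/methods.md` for the model assumptions, parameter
rationale, and numerical choices.

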