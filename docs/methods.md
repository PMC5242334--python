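# Methods

## The sampling problem

A flexible molecular system at temperature `T` samples the canonical
distribution `P_c(E, T) ∝ n(E) exp(−E / R T)`, where `n(E)` is the density
of states of the potential energy `E` and `R` the gas constant
(1.987204×10⁻³ kcal/(mol·K) throughout; energies in kcal/mol, lengths in Å,
temperatures in K, time in fs for chain models and reduced units for the
abstract models). Conventional dynamics at a single `T` rarely crosses
barriers much larger than `R T`. Multicanonical sampling replaces the
physical energy by

    E_mc(E) = R T_sim ln n(E),

so that dynamics at the fixed simulation temperature `T_sim` (300 K here)
produces a *flat* energy histogram over the covered range: the walker
behaves like a canonical ensemble at every effective temperature in the
design band at once, and the flatness of the histogram is itself the
convergence diagnostic. Forces follow by the chain rule,
`f = −(dE_mc/dE) ∇E`, which is why the tabulated `E_mc` carries a
continuous first derivative.

## Virtual-system coupling

Converging one global flat histogram is slow. The V-McMD construction
couples the physical system to a discrete auxiliary variable — the
*virtual state* `v_i`, `i = 1…n_vs` — that confines `E` to an energy zone
`Z_i = [E_min_i, E_max_i]`. Zones ascend, adjacent zones overlap, and
next-nearest zones are disjoint. Every `N_int` MD steps a Metropolis move
proposes `v_i → v_i±1` (± with probability ½ each; an out-of-ladder
proposal is rejected, keeping the proposal kernel symmetric); the move
never alters coordinates. In the hard-wall idealization the acceptance is
exactly 1 when the current energy lies inside the proposed zone and 0
otherwise — this is the rule `virtual_transition` and
`transition_acceptance` implement. Each state only needs to flatten its own
narrow band, which converges much faster, and the union of states covers
the whole range.

### Confinement walls and the sampler's acceptance rule

The confinement mechanism is a design choice here: a differentiable
half-harmonic wall in energy space, `c (E − boundary)²` outside the active
zone (strength `c = 25 (kcal/mol)⁻¹` by default), whose restoring slope
saturates beyond an overshoot `WALL_CAP` (harmonic-to-linear wall). The
saturation is a numerical necessity — an unbounded harmonic wall in `E`
makes the effective force stiffness grow with the overshoot and is
nonlinearly unstable at fixed time step. The effective cap is further
limited by the model's `force_scale_limit` (the largest total force
multiplier it integrates stably at its default step: 25 for the quadratic
toys, 10 for the coarse-grained chain with its anharmonic contact cores).

Because the walls are soft, the internal sampler accepts state hops with
`min(1, exp(−(wall_new − wall_old)/R T_sim))` instead of the sharp rule.
The two coincide wherever zones are meaningful (acceptance 1 inside
overlaps, ≈0 deep inside a foreign zone), but only the wall-consistent
form satisfies detailed balance of the joint (configuration, state) chain;
with the sharp rule the wall shoulders drain asymmetrically, which showed
up as a reproducible ~0.08 kcal/mol bias in the double-well basin free
energy before the change.

With detailed balance, the joint stationary density is
`π(r, v) ∝ exp[−(E_mc(E(r)) + wall_v(E(r)))/R T_sim]`, and the pooled
energy marginal carries the analytically known multiplicity

    m(E) = Σ_v exp(−wall_v(E)/R T_sim)

(exactly 2 inside overlaps, 1 in zone interiors, soft shoulders between).
All pooled diagnostics and all canonical weights divide this factor out.
This is also how the per-state distributions are integrated into one
`P_mc(E)`: the least-squares overlap-matching merge is provided as well
(`merge_state_distributions`), but the `1/m(E)`-weighted pooled histogram
is the lower-noise estimator (scale fitting in narrow overlaps adds ~10%
apparent non-flatness on a truly flat benchmark run) and is what the
flatness metric and `E_mc` updates use.

## Estimating and refining E_mc

`n(E)` is unknown a priori and bootstrapped from canonical runs at several
temperatures spanning the design band (280–600 K, four rungs by default):
each run contributes `ln n(E) = ln h_T(E) + E/(R T)` up to a constant, the
constants are fixed by weighted least squares in the histogram overlaps,
and the stitched curve is smoothed. Two estimator details matter:

* **Smoothing.** Histogram noise along a trajectory is serially
  correlated, so automatic smoothing selectors (GCV) under-smooth badly
  (slope errors of ~30% on the harmonic benchmark versus ~4% with a fixed
  budget). The package fits a weighted least-squares cubic B-spline with
  interior knots at count quantiles: two knots per canonical temperature
  segment for the initial estimate (each histogram constrains the curve
  over roughly its own width), eight knots for refinement updates.
* **Tails.** The covered range is trimmed to the pooled 0.2–99.8%
  quantile band and bins with fewer than 8 counts are excluded:
  `E[ln h]` underestimates `ln λ` for small Poisson counts, which
  systematically flattens the estimated density of states in the tails
  and (via a too-small slope) turns the top of the range into an
  artificial downhill.

Outside the grid, `E_mc` extrapolates linearly at the boundary slope —
canonical tails at effective boundary temperatures — so no runaway forces
occur. The interpolant through the tabulated values is a natural cubic
spline (grid nodes reproduced exactly).

Refinement follows the flat-histogram fixed point: after a sampling cycle,

    E_mc' = E_mc + R T_sim ln P_obs(E),

with `P_obs` the multiplicity-corrected observed density, smoothed as
above, anchored so `E_mc` at the grid midpoint is unchanged between
iterations. Inside the iteration driver, cycles that covered only part of
the ladder still update over the covered bins (the correction is
interpolated/extended elsewhere); the public `update_emc` keeps the strict
≥80% coverage precondition.

## The iteration protocol

`iterate_vmcmd` is the full workflow: canonical seeding, initial `E_mc`,
then alternating TTP production / update cycles. TTP (trivial trajectory
parallelization) runs many independently seeded walkers under identical
weights and pools their snapshots; each walker owns counter-based Philox
streams keyed by `(seed, run_id)`, so pooled statistics are independent of
merge order and a batch reproduces the corresponding single runs bit for
bit. Start conformations are decorrelated snapshots of the (hot-first)
canonical seed runs — the randomization role of a high-temperature
preparation run — with initial virtual states spread round-robin over the
zones compatible with each start energy. Successive cycles chain each
walker's final snapshot; a walker that ended in a wall excursion or on a
transient energy spike restarts from the zone containing its energy or
from its run's most recent in-ladder snapshot. The first 20% of each cycle
is discarded as burn-in (the start-up transient visibly tilts the flat
histogram otherwise). Iteration stops when the merged histogram over the
analysis window — by default the band between the canonical mean energies
at the coldest and hottest seed temperatures — is flat to the target
relative standard deviation (and, optionally, when every state's in-zone
histogram meets a per-state target, which is the sharper convergence
statement); exhausting the schedule flags the result non-converged rather
than raising.

## Reweighting and landscape analysis

A snapshot of energy `E` from the converged run represents the canonical
ensemble at any `T` inside the design band with weight

    w(E) ∝ exp[E_mc(E)/(R T_sim) − E/(R T)] / m(E),

which is exact for equilibrium sampling under whatever `E_mc` was used —
convergence to perfect flatness improves statistics, not correctness.
Temperatures outside the band are refused. Ensemble averages carry a
block-bootstrap standard error with whole runs as blocks (200 resamples).

Conformations are featurized as the vector of all pairwise site distances
(`N(N−1)/2` components). The weighted covariance of these features is
diagonalized; eigenvalues in descending order give contribution ratios
`rc_i = λ_i / Σλ_j`, and the overall conformational spread is
`σ = (Σ_i Var q_i)^{1/2}` (equal to the square root of the eigenvalue
sum). Projections onto the first two principal axes are raw scalar
products without mean subtraction, so external reference conformations can
be placed on the same landscape. The potential of mean force is
`F = −R T ln P(x_PC1, x_PC2)` on a weighted 2-D histogram (default 60×60
cells over the weighted 1st–99th percentile extent per axis, padded 5%;
outliers beyond an automatic grid drop their weight), zeroed at the
occupied minimum; empty cells are unreachable (NaN), never 0. Basins are
labelled by steepest-descent watershed over the 8-neighbourhood with
deterministic tie-breaks, merging basins whose separating barrier (saddle
above the shallower minimum) is below a cutoff.

## Model systems and what they do (not) represent

* **Harmonic well (d = 6 default):** `n(E) ∝ E^{d/2−1}` analytically, so
  the DOS estimator, the flat-histogram claim and reweighting
  (equipartition `⟨E⟩ = (d/2) R T`) all have closed-form targets.
* **Quartic double well** (barrier 3 kcal/mol, separation 2 Å, asymmetry
  1 kcal/mol, one extra harmonic dimension in the benchmark): basin
  partition functions by 1-D quadrature give an exact free-energy
  difference. Its density of states has genuine curvature kinks (second
  basin opening, barrier top) that no smooth `E_mc` representation can
  follow, so the energy histogram plateaus around ~0.15 relative standard
  deviation; the benchmark therefore sets its stopping target below the
  plateau so the full schedule — ending in a long production cycle —
  always runs. Basin equilibration, not histogram flatness, limits the
  answer.
* **Coarse-grained peptide chain** (one site per residue; harmonic bonds
  r₀ = 3.8 Å, harmonic angles θ₀ = 110°, a helix-biasing torsion
  `amp (1 − cos(φ − 50°))`, soft-core Lennard-Jones contacts between
  sites ≥3 bonds apart, σ = 4.5 Å): a bistable stand-in for a short
  disordered peptide, with a compact helix-like family against looser
  extended/hairpin-like families. The soft core keeps energies finite for
  any finite input. V-McMD cycles integrate it at 1 fs (canonical runs at
  the 2 fs default).
* **Hybrid mixing** `E(ω) = (1−ω) E_a + ω E_b` interpolates two
  parameterizations with a single weight, the same convex-combination rule
  hybrid force fields use.

None of these models have solvent, realistic force-field terms, or
chemically specific side chains; passing the benchmarks demonstrates the
correctness of the sampling and analysis machinery, not the fidelity of
any real peptide's landscape. Toy-model masses are not physical: they are
set so the stiffest mode satisfies `ω·dt ≲ 0.05–0.1` at the default step,
which keeps the integrator's configurational bias below sampling noise (a
visible ~40% tilt of the flat histogram appears at `ω·dt ≈ 0.1` per the
multicanonical-rescaled stiffness — measured on the harmonic benchmark
before the masses were fixed).

## Integrators

Langevin (BAOAB splitting) is the default thermostat — robust and ergodic
on stiff low-dimensional systems — with friction 0.1 per reduced time unit
for the abstract models and 1/ps for chain models. The `velocity-scaling`
thermostat is velocity Verlet plus stochastic global rescaling of the
kinetic energy toward its canonical distribution (time constant
`scaling_time`, default 100 dt); unlike crude periodic rescaling it
samples the canonical ensemble, so both thermostats reproduce the same
canonical means. Trajectory divergence (non-finite energy) raises an
error naming the step.

## Numerical choices and degenerate inputs

* Flatness metric: relative standard deviation of histogram counts over a
  window, outermost bin at each edge excluded (wall shoulders and window
  edges would otherwise dominate); zero means perfectly flat.
* Ladder geometry: equal-width zones, default overlap fraction 0.25 of the
  zone width; overlap fraction ≥0.5 would break next-nearest disjointness
  and is rejected. `N_int = 10` steps by default.
* Zone-violation tolerance: the overshoot where the wall energy reaches
  12 R T_sim (exceedance ≈ e⁻¹² per snapshot); anything beyond is counted
  a violation.
* PCA on fewer than two samples, zero total variance, and empty site
  selections raise dedicated errors; a single-sample σ is 0 with a
  warning. Eigenvalue ties and watershed plateaus break toward the lower
  flat cell index, making basin labels deterministic.
* All serialized artifacts are versioned plain text with 17-significant-
  digit floats (bit-exact round trips) and carry the record count, so
  truncated files are rejected rather than partially loaded.

## Benchmark problem sizes

The shipped protocols (`vmcmd.benchmarks`) use: harmonic — 4 seed
temperatures × 100k canonical steps, up to 4 V-McMD cycles of 60k steps
with 24 walkers; DOS recovery — 2 × 3 temperatures × 300k steps;
double well — 3 × 20k refinement cycles plus a 200k-step production cycle
with 24 walkers; CG chain — 5 × 30k cycles plus 60k production with 16
walkers. These sizes were chosen so each benchmark's statistical error
sits well inside its tolerance while the whole suite remains a
minutes-scale desk computation.

## Known limitations

* The stitched-histogram DOS estimator and the update rule are this
  package's own realization of the multi-temperature seeding / iterative
  refinement workflow; published variants differ in detail and are not
  reproduced verbatim.
* Smooth `E_mc` representations cannot flatten systems whose `ln n(E)`
  has kinks (the double well); the method still reweights correctly.
* Reweighting assumes equilibrated sampling under the current `E_mc`;
  slow conformational modes (basin exchange at low energy) are the
  practical accuracy limit and are only diagnosed, not corrected, by the
  flatness metric.
* The CLI's `vmcmd` subcommand runs a single trajectory; multi-run
  production from the command line goes through `iterate`.
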