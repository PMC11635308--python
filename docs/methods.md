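# Methods

## Model

`thermolv` simulates interspecific competition among species whose
intrinsic growth rates depend on a fixed environmental temperature *T*.
The dynamics are the classic shared-sum Lotka–Volterra competition
equations,

    dN_i/dt = r_i(T) · N_i · (1 − Σ_j N_j / K_i),

i.e. all pairwise competition coefficients equal 1: every species is
suppressed by the same total density. This is implemented exactly as
written, not as a general interaction matrix. Assumptions inherited from
that structure: no demographic stochasticity, no spatial refugia, no
temperature dependence in anything but the growth rate (encounter,
consumption and movement rates are constant), and fixed phenotypes — no
evolution within a run.

Two exact consequences are used as oracles throughout the test suite:

* **Logistic closed form** (n = 1): N(t) = K·N0·e^{rt} / (K + N0(e^{rt}−1)).
* **Composition law** (equal K, positive rates): dividing any two
  equations gives d ln N_i / d ln N_j = r_i / r_j, constant in time, so
  ln(N_i(t)/N_i(0)) / r_i is identical across species along the whole
  trajectory and final densities are N_i* = N_i(0)·g^{r_i} for one
  community-wide scalar g. With equal initial densities the steady-state
  ranking therefore equals the growth-rate ranking at *T*; this is what
  links the dominance maps to the curves themselves.

## Thermal performance curves

The default functional form is the Yan–Hunt beta curve

    r(T) = r_peak · ((t_max − T)/(t_max − t_opt)) · ((T − t_min)/(t_opt − t_min))^β,
    β = (t_opt − t_min)/(t_max − t_opt),

chosen because it satisfies every qualitative constraint with the fewest
parameters: unique maximum exactly `r_peak` at `t_opt`, zeros at both
limits, and asymmetry governed purely by the spacing of the cardinal
temperatures. The skewness summary is (t_max − t_opt)/(t_opt − t_min);
values below 1 are the empirically typical right-skewed shape. A second
registered form (`gaussian`: anchored Gaussian rise, quadratic fall) exists
for sensitivity checks; the registry is extensible.

Outside the support: below `t_min` the rate is clamped to 0 (cold arrests
growth), while above `t_max` the rate extends linearly negative with slope
`death_slope` (default 0.1 per °C per unit time) — organisms near their
upper critical temperature face maintenance costs and death, and this is
what drives warm-side extinctions. Setting `death_slope = 0` restores a
flat zero beyond `t_max`.

Default community (peaks normalized to 1 per unit time, shared
`t_min` = 0°C):

| species | t_opt (°C) | t_max (°C) | skewness |
|---------|-----------|-----------|----------|
| S3      | 32        | 37        | 0.156    |
| S1      | 37        | 41        | 0.108    |
| S2      | 42        | 46        | 0.095    |

S1's optimum sits at the 37°C environmental ceiling, S2 above it, S3
below. Capacities are equal (K = 1): under shared-sum competition, unequal
capacities force exclusion by the largest-K species at every temperature,
which would erase the temperature signal entirely — the coexistence
structure of interest exists only on the equal-K manifold, and this
sensitivity is the model's, not an implementation choice. Initial
densities are equal at 0.01·K, which makes the composition law the ranking
mechanism. Time units are arbitrary; rates are "per unit time".

## Steady-state integration

`scipy.integrate.solve_ivp` with LSODA (stiffness-switching), an analytic
Jacobian, rtol 1e−8 and atol 1e−12. Steady state is a **derivative**
criterion — terminate when max_i |dN_i/dt| < 1e−9 (density/time), via a
terminal event — with a horizon of 10⁴ time units as backstop and a
`converged` flag recording which fired. A state-difference criterion would
be wrong here: the equal-K system converges to a neutrally stable manifold
Σ N = K on which densities still creep.

Extinction handling: densities below 1e−9·K̄ are reported as exactly 0, as
is any species whose growth rate at *T* is strictly negative and which has
declined below its initial density — its exact t→∞ limit is 0, but a
derivative threshold alone would strand it at ≈ deriv_tol/|r|. If the rate
vector makes the initial state already stationary (e.g. every rate is 0 at
that temperature), the integrator is skipped and the initial densities are
returned unchanged, converged at t = 0.

## Temperature sweep and dominance

The "continuous" 25–45°C range is discretized at 0.1°C (201 points;
configurable), each temperature an independent cold start from the same
initial densities — the sweep maps equilibrium outcomes, not a warming
trajectory. Per grid point the dominant species is the strictly largest
density; the top two within 1e−6 relative is reported as a tie, never
silently broken, and universal extinction as "none". Dominance intervals
are maximal runs of grid points sharing a dominant.

## Scenario ensemble

The generator emulates known interspecific variation in thermal
performance curves as seeded uniform draws over declared ranges, one
factor at a time (a combined-axes mode is deliberately absent):

* **skew**: one skewness value per scenario drawn from [0.05, 0.8],
  applied to all species by moving `t_min`/`t_max` around each fixed
  `t_opt` with thermal breadth preserved. A common value (rather than
  independent per-species draws) keeps "magnitude of skewedness" a single
  monotone dial; independent draws can place one species' rising tail
  under another's falling tail and produce multiple in-grid curve
  crossings, which is a different experiment (curve-shape *divergence*)
  than the one scored here.
* **spacing**: a gap drawn from [2, 8]°C; optima are re-centred on the
  middle species' optimum (a 5°C draw yields 32/37/42) by rigid curve
  shifts, preserving each curve's skewness.
* **normalization**: per-species peak rates drawn from [0.5, 2], rescaled
  back to a common peak when `normalize` is true (the default), left as
  drawn otherwise.
* plus every pairwise matchup of the base community.

Draws violating `t_min < t_opt < t_max` are rejected, logged, and redrawn
(the bundled rules cannot violate it; the guard protects custom ranges).
Identical spec and seed reproduce the ensemble bit-for-bit.

Each scenario's sweep is scored with four flags: **monotone hand-over**
(dominant species' optima non-decreasing along the grid), **middle-species
persistence** (the median-optimum species holds > 1% of total density at
every grid point where its growth rate is positive; for two-species
communities, the lower-optimum member), **complete hand-over** (every
species dominates somewhere), and **any tie**. Within the ranges above,
all scenarios preserve monotone hand-over and persistence. The regime
boundaries are operationalized through the flags rather than asserted as
numbers: spacing below ~0.003°C makes steady-state densities
indistinguishable at the 1e−6 tie tolerance (the composition law gives a
relative density gap ≈ G·c·s²/2 ≈ 0.1·s² at spacing s, with G the shared
log-growth factor and c the curve's log-curvature at the optimum), and
spacing beyond ~17°C pushes the cold species' `t_max` out of the grid so
the hand-over is never complete.

### What the generator does and does not emulate

It varies curve shape, optimum spacing and peak height around a plausible
mesophile community — the axes the robustness claim is about. It does not
emulate measurement noise, curve-fitting uncertainty, unequal carrying
capacities, correlated trait draws, or empirical TPC databases; passing
the battery shows the dominance pattern is a structural consequence of
skewed unimodal curves under shared-sum competition, not that any
particular real community behaves this way.

## Problem sizes

Defaults throughout: 201-point grid; 10 draws per axis + 3 pairwise = 33
battery scenarios; 100 random communities for the conservation-law check.
The unit-test suite reuses the same machinery on coarser grids (0.2–1°C)
and smaller ensembles; the acceptance layer runs the full sizes.

## Known limitations

* Unequal capacities make the outcome temperature-independent (largest K
  wins); the package permits them but the dominance analysis is only
  meaningful at equal K.
* The neutral manifold means absolute steady-state densities inherit a
  weak dependence on the integrator tolerance; ratios (shares, rankings)
  are governed by the exact composition law and are tolerance-robust.
* A species sitting exactly at a zero of its curve (T = t_min or t_max)
  is frozen at its initial density — a measure-zero edge on real grids but
  visible at round default temperatures (S3 at exactly 37°C).
* The linear death extension is a modelling convenience; nothing is
  claimed about the rate of decline above t_max beyond its sign.
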