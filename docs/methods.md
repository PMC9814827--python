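# Methods

## Model

The testa is a thin, linearly elastic spherical shell of dimensionless
radius `r = R/h` (radius over wall thickness) and effective rigidity `k`,
loaded by the dimensionless endosperm turgor `p(t)`.  For a thin
pressurized shell, wall tension scales as `p·r` (Laplace) and elastic
strain as `p·r/k`.  The model couples two mechanosensitive laws:

* irreversible, Lockhart-type expansion at a rate proportional to the
  strain in excess of a threshold: `ṙ = (p·r/k − 1)₊ · r`.  The threshold
  is absorbed into the unit of strain by the nondimensionalization; it is a
  model constant, not a parameter.  `ṙ ≥ 0` always — growth never reverses.
* first-order relaxation of the rigidity toward a stress-dependent target:
  `k̇ = γ(1 − k + α·H_η(p·r, ρ))` with the Hill response
  `H_η(x, ρ) = x^η/(x^η + ρ^η)`.  The unstressed target is 1 (the rigidity
  unit); full mechanoinduction raises it to `1 + α`.

`ρ` is the half-activation stress of stiffening measured in units of the
growth threshold; `γ` compares the stiffening and growth time scales; `η`
sets how switch-like the mechanotransduction is.  Pressure enters only
through the product `p·r`, so scaling `p` by `c` and `r` by `1/c` leaves the
rigidity dynamics unchanged and rescales the radius exactly — pressure is a
control input, not a system property.

Assumptions: homogeneous isotropic single-layer wall, spherical symmetry
(scalar stress/strain rather than tensor fields), instantaneous elastic
equilibrium, and no osmoregulatory feedback of growth on pressure.

## Steady states

A steady state requires `ṙ = 0` with `k` on its nullcline, which reduces to
one equation in the wall stress `x = p·r`:

    g(x) = 1 + α·H_η(x, ρ) − x = 0.

All roots lie in `(0, 1 + α]`; the root set depends only on `{α, ρ, η}`,
never on `p` — pressure rescales the radius at which a given steady stress
is reached but not the existence of arrest.  `solve_fixed_points` locates
roots by a sign scan on a log-dense grid (2×10⁴ points) refined by Brent
bisection to 1e-12; a near-zero dip of `g` without a sign change at grid
resolution is flagged as a suspected tangency and not resolved further
(a measure-zero case irrelevant to sweeps).  A root with Hill contribution
`α·H(x*) ≥ 0.1` counts as a stiffening-mediated arrest; the residual
balance just above `x = 1`, where stiffening is essentially inactive, is
reported but flagged trivial.

Two arrest modes exist and are distinguished in the tests:

* **overshoot arrest** — `k` overtakes `x` from below; the radius freezes
  strictly below the root, strain drops under the threshold in finite time;
* **soft landing** — with fast stiffening `k` tracks its nullcline and the
  trajectory creeps into the fixed point with strain approaching the
  threshold from above; the final stress equals a root but the approach is
  asymptotic.

## Integration and outcome classification

Fixed-step classical RK4 (default `dt = 0.005` in the grid's time unit).
The system is non-stiff away from blow-up, and a fixed grid makes batch and
single evaluation exactly equivalent.  Events:

* **divergence** — `r > 100·r₀` (biologically relevant arrests are below
  4×, so 100× is unambiguous runaway) or a non-finite state;
* **rate criterion** — both dimensionless rates `|ṙ|/r` and `|k̇|` below
  `steady_tol = 1e-6` (far below data noise); the state is then frozen for
  the remaining grid so all trajectories share the full time grid;
* **arrest latch** — an exact no-return test for non-increasing pressure
  inputs with infimum `p_inf`: if strain ≤ 1 and `1 + α·H(p_inf·r) ≥ p·r`,
  growth can never resume.  Proof sketch: while strain ≤ 1 the radius is
  frozen, future stress values satisfy `x(t) = p(t)·r ≤ p·r`, and `k`
  relaxes among targets all ≥ `1 + α·H(p_inf·r)` ≥ every future `x(t)`,
  starting from `k ≥ x`; hence strain stays ≤ 1 forever.  The latch decides
  the outcome immediately (the series integration continues so the rigidity
  series stays honest).

Outcomes: `no_growth` (strain never exceeded the threshold), `converged`
(grew and reached, or is irrevocably bound for, a steady state),
`diverged`, `unresolved` (fate undecided at the horizon).

Soft landings approach the fixed point asymptotically — strain stays above
the threshold at every finite time — so no within-horizon event fires for
them.  The batch classifier therefore resolves fate past the horizon: it
continues in dimensionless time at the limiting pressure `p_inf` (step
0.02, budget 2000 time units) until one of the same events fires.  The
extension decides the outcome only; all reported radii are within-horizon
values.  Without this, the slowly-arresting trajectories that best match
smooth growth data are systematically misclassified as unresolved and the
fitting pipeline selects only sharp, poorly-fitting arrests.

Two closed forms serve as oracles: with stiffening off (`α = 0`, `k₀ = 1`)
the growth line integrates to `r(t) = 1/(p + (1/r₀ − p)e^t)` with finite
blow-up at `t* = ln(p·r₀/(p·r₀ − 1))`; with growth disabled the rigidity
relaxes as `k(t) = k_∞ + (k₀ − k_∞)e^(−γt)`, `k_∞ = 1 + α·H`.

The hot loop (`numba`-compiled, shared by the single-trajectory and batch
paths) evaluates the Hill response as `z/(1+z)` with `z = (x/ρ)^η`,
saturating to 1 when `z` overflows.

## Fitting pipeline

Rejection-style: sample, simulate, filter, score, select.

* **Sampled quantities and default ranges** (log-uniform unless noted):
  `α ∈ [0.5, 20]`, `γ ∈ [0.1, 50]`, `η ∈ [1, 30]`, `ρ ∈ [0.5, 10]`, time
  scale `τ ∈ [0.5, 5]` days per dimensionless unit, and initial stress
  `x₀ = p(0)·r₀ ∈ [1.01, 1.5]` uniform.  `k₀ = 1` (the unstressed rigidity
  fixed point) and `p = 1` for constant-pressure sweeps — only the product
  `p·r` matters, so a pressure scale is redundant with `x₀`.  `τ` is
  sampled because the model is dimensionless while data live on a day axis;
  nothing in the model fixes the mapping.
* **Filter**: outcome `converged` with relative radius at 10 days inside
  the inclusive band `[3.0, 4.0]` (the biologically relevant 3.5 ± 0.5
  fold change).
* **Score**: RMSE between the simulated relative radius at integer days
  0–10 and the dataset's per-day mean relative radius — the minimal
  faithful score on the plotted quantity.  Survivors are ranked by
  (score, sample index) and the best 100 retained.
* **Marginals**: histogram with fixed 0.25-wide bins anchored at 0 on the
  parameter's natural scale; ties resolve to the lowest bin; the bin
  center and median are reported.

The fit landscape is sloppy: near-equivalent fits exist across wide ranges
of `ρ` (with compensating `α`, `η`, `γ`), because the data constrain the
effective stiffening response over the traversed stress window rather than
the Hill parameters individually.  Top-100 marginals should be read as
"which regions of the sampled box are compatible", not as parameter
estimates.

Batch sweeps integrate on the day grid (`dt = 0.005` d; per-set factor
`1/τ` converts to dimensionless rates), recording the radius at integer-day
checkpoints; a 5×10⁴-set sweep takes seconds and 5×10⁵ under a minute on
one core.

### Downstream experiments on the retained ensemble

* **Sensitivity scan**: each stiffening parameter `{α, ρ, η}` scaled by
  1 + δ, δ on a 9-point grid in [−0.2, 0.2], under both genotype drops;
  influence = range of the median final relative radius across δ.
* **Pressure-drop swap**: rerun under the five drop functions; reports
  mean ± sd growth curves, mean rigidity, per-set final radius, and the
  stiffening half-time (first time the rigidity crosses halfway from its
  initial to its final value).
* **Constant-pressure (osmotic) scan**: factors 0.5–1.5 of the fitted
  pressure with the fitted initial radius kept; reports per-set outcome,
  final relative radius, and initial growth rate (day 0→1 relative-radius
  gain).  Medians are the robust summary: at the highest factors a few
  percent of sets tip over the divergence boundary and would dominate a
  mean.

## Pressure inputs

Constant, descending-logistic drop
`p(t) = p_end + (p_start − p_end)/(1 + e^{(t − t_mid)/w})`, pointwise
linear mixtures, and multiplicative scaling.  The logistic is the simplest
smooth monotone drop with interpretable start/end/midpoint/width; its four
parameters are fitted to stage-binned pressure means by multi-start
(20 seeded starts) trust-region least squares, with constant data returning
a flagged degenerate drop.  Default normalized drops — calibration
constants, not measurements: wild type 1.0 → 0.55, *iku2* 1.0 → 0.85, both
with midpoint 4 d and width 1 d; the wild-type drop must be strictly deeper
(the measured genotype ordering is enforced).  Embryo stages map to day
midpoints preglobular 1.5, globular 3.5, triangular/heart 5.5, torpedo 8
(declared, overridable).

## Measurement arithmetic

Turgor from indentation inverts the thin-shell relation
`F = π·P·δ/c_M`: the slope of the loading segment is fitted by ordinary
least squares through the origin (the model is linear with zero intercept)
and `P = slope·c_M/π`.  Curvature radius from fitted ellipse axes is
`RC = major²/minor`; mean curvature is the arithmetic mean of the two
principal curvatures `(1/RC_long + 1/RC_trans)/2`, computed per seed.
Seed radius from projected area uses the circle idealization
`Area = π·radius²`; per-genotype relative radii are normalized by the
day-0 mean radius.  Relative growth rate is
`(Area(day n) − Area(day n−1))/Area(day n−1)`.

## Synthetic data generators

The growth generator draws per-seed relative radii
`curve(d)·(1 + ε)`, `ε ~ N(0, cv)` truncated at −0.5, around the logistic
`curve(d) = 1 + A·(σ(d) − σ(0))/(1 − σ(0))`.  Wild-type preset:
`A = 2.5` (anchored to the ~3.5-fold radius increase), `t_mid = 2.4` d and
`s = 1.2` d calibrated once so the noiseless curve first reaches 98% of its
10-DPA value at day 7 and its day-over-day growth-rate peak falls in days
1–3; `cv = 0.08` (a declared default; true per-seed dispersion is not
published numerically); per-day sample sizes follow the study's counts
(428–529 per day).  *iku2* preset: `A = 2.1`, `t_mid = 2.2` d, `s = 1.0` d —
similar early growth, earlier and smaller arrest.  The pressure generator
draws per-seed normalized pressures `N(mean, 0.08)` (positive-truncated)
around stage means (1.00, 0.90, 0.70, 0.55) for the wild type and (1.00,
0.95, 0.88, 0.85) for *iku2*, with the wild-type decline strictly deeper by
construction.

What the generators emulate: population curve shape, per-day/per-stage
sample sizes, genotype ordering, and multiplicative measurement scatter.
What they do not: between-experiment batch effects, day-to-day correlation
within a silique, censoring/staging errors, or the real dispersion shape.
Passing tests therefore demonstrate that the pipeline recovers structure it
is designed to detect under idealized noise, not that the model is
identified on real measurements.

## Numerical choices and degenerate inputs

* RK4 step 0.005 (dimensionless or days); halving the step changes a
  converged final radius by < 1e-6 relative.
* Divergence cap 100×r₀; outcome classification is invariant to caps in
  [50, 200] for converging trajectories.
* Hill evaluation via `(x/ρ)^η` with overflow-saturation to 1.
* Drop fitting: parameters `(p_end, depth ≥ 0, t_mid, log w)` with bounds,
  best of 20 seeded starts by residual.
* Degenerate inputs: constant pressure data → flagged constant drop;
  empty top-K → error; fewer survivors than `top_k` → all survivors with a
  warning flag; zero-length sweeps → empty result tables.
* Ties in top-K selection break by sample index; histogram-mode ties take
  the lowest bin.

## Problem sizes

The shipped analyses use 5×10⁴ parameter sets for fits and 5×10⁵ for the
selectivity count — the sizes at which the headline numbers are quoted; the
example scripts use 10⁴ sets to stay interactive.  The selectivity count
scales linearly with the sampled volume, so it is only meaningful relative
to the documented default ranges.

## Known limitations

* Scalar elasticity: no tensorial stress/strain, no multi-layer testa, no
  wall-composition chemistry; stress is strictly proportional to pressure,
  which makes simulated growth more sensitive to the drop depth than real
  seeds.
* The best-fit "plateau day" (first integer day at ≥ 98% of the 10-DPA
  value) is a fragile statistic of a single selected simulation; across
  sweep seeds it varies by ±2 days even when the fitted curves are visually
  indistinguishable.
* Top-100 marginal modes depend on the sampled box via the sloppiness
  described above; with the default broad ranges the `ρ` marginal peaks
  near the steady-state stress (~3.5–4 in threshold units) rather than at
  the growth threshold.
* The arrest latch is exact only for non-increasing pressure inputs; all
  shipped inputs (constants, drops, their mixtures and scalings) satisfy
  this, but a user-supplied increasing pressure would fall back on the
  rate criterion alone.
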