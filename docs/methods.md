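# Methods

## Models and the semi-analytic reduction

The package works with the standard SIR/SEIR compartmental models for a
closed population (no births, deaths or waning immunity), in population
fractions, with exponentially distributed stage durations.  All rates are
per day and all times in days.  A model instance is defined by the basic
reproduction number ℛ₀ (> 0), the recovery rate γ (infectious period
D = 1/γ), the incubation rate σ (incubation period D′ = 1/σ), and the
initial seed fractions I₀ ∈ (0, 1) and E₀ ∈ [0, 1); the initial recovered
fraction is always 0, so S₀ = 1 − I₀ − E₀.  The transmission rate is
β = ℛ₀γ.  The SIR model is represented as the σ = ∞ member of the SEIR
family (stretch factor α = σ/(σ+γ) = 1) rather than a separate type, so
every operation handles both models; the parameter constructor accepts
`sigma=None` as that sentinel.

For SIR, differentiating S′ = −βIS and eliminating I produces a Bernoulli
equation in φ = 1/S′ whose solution gives I(S) and R(S) in closed form and
time as one quadrature — an exact semi-analytic solution whose only error
is numerical.  For SEIR the same route is blocked unless R‴ = 0 is imposed,
which replaces the pair (σ, γ) by the single product αγ in the reduced
equation.  The resulting closed forms E(S), I(S) conserve S+E+I+R = 1
identically and collapse onto the SIR forms at α = 1; R(S) = (γ/β)ln(S₀/S)
is exact for both models.  The closed-form I(S) is maximal at S = 1/ℛ₀, so
the peak time is the t(S) quadrature evaluated there, and factoring αγ out
of that quadrature shows the dimensionless αγΔt depends (to the accuracy of
the approximation) only on ℛ₀ and I₀.

Assumptions worth keeping in view: the R‴ = 0 closure is an early/late-time
idealisation, not a controlled expansion — its absolute-time error grows as
the exposed stage lengthens relative to the infectious one (small α); and
the "peak at S = 1/ℛ₀" statement inherits the quasi-stationarity
approximation I′ = E′ = 0, so the true ODE peak occurs at a slightly
different S.  Both the semi-analytic peak and the ODE-measured peak are
exposed; ensemble experiments use the ODE one.

## Numerical choices

* **Time quadrature.**  The t(S) integrand has a boundary layer of width
  ~I₀ at S = S₀ (its denominator is βS₀I₀ there), so the integral is
  evaluated on u = ln(S₀/s), where the layer sits at u = 0 and the
  integrand is smooth; adaptive Gauss–Kronrod quadrature
  (`scipy.integrate.quad`) with absolute and relative tolerance 1e-10 and
  a 200-interval budget then resolves it without special handling.  A
  result whose error estimate exceeds ten times the request raises a
  quadrature error carrying the achieved estimate.  The integrand is
  singular exactly at I₀ = 0, which is why a strictly positive seed is a
  validated precondition.
* **The printed dimensionless peak integral.**  The variant of the peak
  integral with the I₀ term dropped from the integrand is log-divergent at
  s = S₀.  It is provided only as a flagged approximation
  (`peak_time_dimensionless(..., drop_i0=True)`) in which the integration
  starts at S₀ − I₀, the point where the dropped term equals the retained
  one; at ℛ₀ = 2, I₀ = 10⁻⁴ it overestimates the regular form by ~8%.
  All peak times elsewhere use the regular, I₀-retaining quadrature.
* **ODE reference.**  `solve_ivp` with DOP853 at rel. tol. 1e-10 / abs.
  tol. 1e-12 (the systems are non-stiff at epidemic scales; conservation
  holds to ≲1e-9).  Integration stops when I falls to I₀/10 after its
  peak, or at t_max = 1000 d, whichever is first, so slow epidemics are
  never truncated mid-wave; the stopping rule can be disabled for
  final-size checks.  The dense solution is sampled at a fixed 0.05 d step
  for reproducible curve comparison.
* **Peak extraction.**  Discrete argmax on the sampled grid; when the
  trajectory carries the integrator's dense output the peak is then
  refined by bounded scalar maximisation of the continuous solution
  (tolerance 1e-10 d), which makes the located Δt independent of the
  sampling step and hence invariant under a common rescaling of all rates;
  for plain sampled trajectories a three-point quadratic interpolant is
  used instead.  A maximum on the final sample of a still-rising curve
  raises a truncation error.  A monotonically declining compartment
  reports Δt = 0 with its initial value — the same "no peak" convention
  used when ℛ₀S₀ ≤ 1, chosen so ensemble sweeps never abort.
* **Trajectory reconstruction.**  Semi-analytic trajectories are built on
  an S-grid log-spaced in u = ln(S₀/s) from S₀ down to where the
  closed-form I reaches I₀/10, pairing each t(S) with the closed-form
  compartments.  Inverting t → S is not needed for any shipped analysis
  and is therefore not part of the public surface.

## The ensemble experiments (synthetic-data generator)

`EnsembleSpec` draws the incubation and infectious *periods* — not the
rates — independently and uniformly from [2, 5] days (`numpy` PCG64,
seeded; the whole pipeline is a pure function of the spec).  The defaults
(100 draws, ℛ₀ = 2, I₀ = 10⁻⁴, E₀ = 0) are the illustration conditions of
the experiments this package replicates; the original peak-time experiment
used 10,000 draws per ℛ₀, and that size remains available
(`--n-draws 10000`), but 100 draws already determine the ensemble CVs to
well within the frozen bounds and keep the default suite fast.  E₀ = 0 is
an assumption — the experiments specify only I₀ — documented here once.
The generator emulates parameter uncertainty only: it does not produce
demographic stochasticity, observation noise, contact structure or
time-varying transmission, so passing ensemble tests says nothing about
fitting real incidence data.

Two experiments:

* **Curve collapse** — each draw's SEIR system is integrated and the
  infectious curves are compared on a common grid (linear interpolation
  onto 2000 points spanning the intersection of time supports), before and
  after the rescaling t → αγt.  The metric is the sup over the grid of the
  (max − min) across curves.
* **Peak-time universality** — for each ℛ₀ on a grid and each draw, Δt is
  measured on the ODE solution and multiplied by that draw's αγ; the
  summary reports mean, SD and coefficient of variation of αγΔt and of
  γΔt per ℛ₀, excluding no-peak draws.

## Calibrated, frozen tolerances

The closure's accuracy is quantified nowhere in closed form, so the
package's approximation bands were measured once against the ODE reference
at σ, γ ∈ {1/2, 1/5} per day and ℛ₀ ∈ {2, 7}, then frozen as constants in
the test suite: closed-form E(S), I(S) within 0.10 of the ODE values at
matched S (worst observed 0.073, at ℛ₀ = 7); semi-analytic t(S) and peak
time within 50% relative of the ODE (worst 0.47 — the closure's absolute
clock is its weakest output); ensemble CV(αγΔt) below 0.05 (observed
≈0.01–0.02, versus ≈0.16 for γΔt — the residual spread is exactly the
Λ²D′D term the closure lacks); collapse spread of rescaled I-curves below
0.08 absolute (observed ≈0.06).

## Growth rates

The closure's growth rate Λ = γℛ₀(I₀ + αS₀) − αγ corresponds to an
exponentially distributed generation time of mean D + D′, while the exact
linearised rate solves (1 + ΛD′)(1 + ΛD) = ℛ₀S₀; the two differ by the
Λ²D′D cross term, and the exact relation is the one that matches a
log-linear fit to the ODE's early infectious growth (to ~0.1%).  Measuring
that rate from a trajectory requires the fit window to sit inside the
linear regime: the shipped check seeds the epidemic at I₀ = 10⁻⁶ and fits
over 10I₀ < I < 10³I₀, i.e. I ≤ 10⁻³, where susceptible depletion is
negligible.  With a larger seed (I₀ = 10⁻⁴) the same relative window
reaches I = 0.1, deep into saturation, and the fitted slope is biased low
by ~20% — a property of the window, not of the relations.

## Known limitations

* Time rescaling aligns the ensemble's curves in *time* but cannot align
  amplitudes.  The SEIR infectious peak height is approximately α times
  the SIR one, so the rescaled I (and E) families retain an
  amplitude spread of order the α spread (measured rescaled sup-spread
  ≈0.06 against ≈0.10 raw, ratio ≈0.55), while the S and R families —
  whose start and end values are α-independent — collapse by more than an
  order of magnitude (ratio ≈0.07).  "Universal shape" is therefore a
  statement about timing, and exact for amplitudes only in the α → 1
  limit.
* The closure degrades for small α; no Erlang-staged compartments,
  demography, vaccination or time-varying parameters are modelled, and the
  package deliberately stops short of fitting real epidemic data.
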