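# Methods

## Model family

The package implements four deterministic, closed-population, non-lethal
epidemic models on a common dimensionless footing (time in units of the mean
recovery time `t_R`):

* **NRDE** — one DDE for the cumulative function `m = (I+R)/N` with two
  delays: the unit recovery delay and the incubation delay `τ_I = t_I/t_R`.
* **NRD** — the `τ_I = 0` reduction (one delay); implemented as the same
  code path, so the reduction is exact to the bit.
* **SEIR / SIR** — the standard ODE references, nondimensionalized the same
  way (`ds/dτ = −R₀si`, `de/dτ = R₀si − e/τ_I`, `di/dτ = e/τ_I − i`,
  `dr/dτ = i`).

Assumptions shared by all four: fixed population, no vital dynamics, no age
structure, constant `R₀`, exponential-free *fixed-duration* residence in the
delay models (an individual is infectious for exactly one recovery time,
latent for exactly `τ_I`) versus exponentially distributed residence in the
ODE models. That distributional difference is exactly why the delay models
peak higher and earlier and end sooner at equal (`R₀`, `τ_I`, `s₀`), while
the final size `r_∞` — which depends only on `R₀` and `s₀` through
`s_∞ = s₀e^{−R₀(1−s_∞)}` — is shared by all four.

### History

A DDE needs `m` on `[−(1+τ_I), 0]`. The default is the jump seeding: `m = 0`
before the outbreak and `m(0⁺) = m₀ = 1 − s₀` (the seed cohort starts
infectious; SEIR mirrors this with `i(0) = m₀`, `e(0) = 0`, switchable to
exposed seeding). `HistorySpec` accepts arbitrary user histories as function
objects; they should be nondecreasing with values in `[0, 1]`.

## Numerics

* **Integrator.** Classical 4th-order Runge–Kutta on a fixed uniform grid,
  method of steps: delayed arguments are served by linear interpolation of
  the stored solution. The history jump propagates derivative kinks at
  `τ_I`, `τ_I+1`, `2τ_I`, …, so no scheme attains formal 4th order here; a
  robust fixed-step scheme with dense storage is used instead and validated
  by step-halving (empirically the max error vs a 8–32× finer reference
  falls monotonically over h = 0.04 → 0.005) and by the final-size oracle.
* **Default step** `h`: 1/100 of the smallest delay present
  (`min(1, τ_I)/100` for `τ_I > 0`, else `1/100`), floored at `1e-4` so a
  tiny positive `τ_I` cannot demand an unbounded grid. `h` is snapped so
  the grid hits the horizon exactly. Delay arguments are *not* required to
  be multiples of `h` (interpolation handles e.g. `τ_I = 1.25`).
* **Extension.** The solver integrates to `horizon + τ_I` so that
  `s = 1 − m(τ+τ_I)` and `e` are recoverable on all of `[0, horizon]`.
* **Half-open history.** The delayed lookup returns `m₀` at exactly `τ = 0`
  and the history value for `τ < 0`, matching the half-open seeding
  interval; this is what makes `i` drop exactly at `τ = 1` in the frozen
  (`R₀ = 0`) case.
* **Invariant enforcement.** The RHS is nonnegative for nondecreasing
  histories, so `m` is monotone and ≤ 1 up to rounding; each step clamps to
  `[previous value, 1]` to keep the guarantees exact. Compartments computed
  from the *same* interpolated values telescope, so `s+e+i+r = 1` holds to
  ~1e-15 pointwise. Everything is deterministic — identical inputs give
  byte-identical outputs.

## Metrics

* `final_size`: `r` at the last grid point, accepted only if `r` moved less
  than `tol` (default 1e-8) over the final unit of time; otherwise an
  explicit "extend horizon" error.
* `epidemic_duration` (`τ_D` at cutoff ε, default 5e-4): the **last**
  down-crossing of ε by `i(τ)`, interpolated linearly between grid points.
  With oscillations `i` can cross ε repeatedly; the last crossing matches
  the reading "the outbreak is over once `i` stays below the tolerable
  endemic level". (`τ_D` vs `R₀` shows the characteristic cusp: here, at
  `s₀ = 0.995`, `τ_I = 1`, ε = 5e-4, the maximum sits near `R₀ ≈ 1.1`.)
* `peak`: global maximum of `i`, earliest time on ties.
* `estimate_initial_growth`: least-squares slope of `ln(value)` vs `τ`.

### Oscillation counting (`oscillation_count`)

Counting raw pre-peak local maxima of `i` cannot separate self-excitation
from two artifacts present in *every* jump-history run: the structural echo
at `τ = τ_I + 1` when the seed cohort recovers, and grid-level ripple. The
rule adopted: count pre-peak maxima with `τ > τ_I + 1` and prominence at
least 1% of the global peak. At `R₀ = 2`, `s₀ = 0.99`, `h = 0.01` this gives
0, 0, 3, 4 undulations for `τ_I` = 0.80, 1.00, 1.20, 1.40 — switching on
exactly where the analytic threshold (1.151) says it should.

### Growth-rate fit window (`growth_fit_window`)

The exponent `β` dominates `m − m₀` only after the history-induced transient
has decayed and before saturation. A fixed window fails across regimes
(slow-growth runs need a later window), so the default window is defined by
*levels*, not times: from where `m − m₀` first exceeds `50·m₀` to where it
reaches `0.01` (so `s ≳ 0.99` throughout). With `s₀ = 0.9999` this
reproduces the characteristic-equation root within 0.01–3.2% across
`R₀ ∈ {1.5, 2.5} × τ_I ∈ {0.5, 1.0}`.

## Oscillation analysis

`γ₀` is computed by solving the stationarity condition `tan x = x` on
`(π, 3π/2)` by bracketed root finding (1e-12), giving
`γ₀ = |sin x*/x*| = 0.2172336…`; a dense grid scan is kept as the test
oracle. Frequencies are roots of `sinc(ωτ_I) + 1/(2R₀τ_I)`, located by a
sign-change scan in `x = ωτ_I` at step π/1000 (finer than any sinc lobe, so
no root is skipped) and refined by bisection.

Because the sinc condition arises from *squaring* the real and imaginary
parts of the characteristic relation, its roots satisfy the full complex
relation only approximately and may bracket rather than hit the true mode:
at `R₀ = 2`, `τ_I = 1.4` the sinc roots are ω ≈ 2.80 and 3.66 while the
exact complex root — available via `refine_mode`, a Nelder–Mead
minimization of the unsquared residual seeded at a sinc root — is
`(α, ω) ≈ (0.0956, 3.324)`, whose period matches the simulated ripple
spacing to ~2%. The package reports the sinc roots unfiltered (they are the
standard `α ≈ 0` result) and exposes the residual and the refiner for users
who want the exact mode. The ansatz amplitudes depend on the history and
are not solved for.

`growth_exponent_beta` solves `β e^{βτ_I}/(1−e^{−β}) = R₀` (left side → 1 as
β → 0⁺ and strictly increasing, so a positive root exists iff `R₀ > 1`);
`tau_I_from_beta` inverts it in closed form, defined while
`β/(1−e^{−β}) < R₀` (otherwise `τ_I ≤ 0`, unphysical).

## Problem sizes used in the tests

Simulation-backed checks run at `h = 0.01` (0.02 for the long near-critical
sweeps) with horizons of 20–60 recovery times, 200–300 for settling and
near-critical-duration checks — long enough for `r` to converge to 1e-8 at
the parameters tested, and small enough that the whole suite runs in a few
seconds. Step-refinement checks use h ∈ {0.04, …, 0.005} against an
h = 0.00125 reference.

## Known limitations

* Fixed-step integration with interpolated delays is ~2nd-order accurate in
  practice across the kink set; adaptive stepping and discontinuity
  tracking are out of scope.
* For `0 < τ_I < h` the inner Runge–Kutta stages clamp the (then advanced)
  delayed read to the current front value; with the default step rule this
  regime is never entered unless the user forces a coarse step.
* The linearized analysis assumes `s ≈ 1`; its predictions degrade as the
  epidemic saturates, which is why growth fitting stops at `m − m₀ = 0.01`.
* No stochasticity, networks, seasonality, age structure, or time-varying
  `R₀`; no forced/controlled variants; no time-discretized map variant.
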