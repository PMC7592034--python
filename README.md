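# delayepi

Deterministic epidemic models built on **delay differential equations**, for
modellers who want SEIR-like dynamics from a single scalar equation — and for
studying the self-excited oscillations that the delays produce.

## The models

Let `m(τ) = (I + R)/N` be the *cumulative function*: the fraction of a closed
population that is or has been infectious. Measuring time in units of the mean
recovery time `t_R`, with basic reproduction number `R₀` and dimensionless
incubation delay `τ_I = t_I / t_R`, the whole epidemic obeys one DDE:

```
dm/dτ = R₀ [1 − m(τ)] [m(τ − τ_I) − m(τ − τ_I − 1)]
```

with history `m = 0` on `[−(1+τ_I), 0)` and `m(0) = m₀ = 1 − s₀`. The
bracketed difference is exactly the infectious fraction a latency ago: every
infection becomes infectious after `τ_I` and recovers one recovery time later.
All four compartments are algebraic reads of `m`:

```
s(τ) = 1 − m(τ + τ_I)    e(τ) = m(τ + τ_I) − m(τ)
i(τ) = m(τ) − m(τ − 1)   r(τ) = m(τ − 1)
```

With `τ_I = 0` this is the single-delay NRD model (the SIR analogue); with
`τ_I > 0` it is the two-delay NRDE model (the SEIR analogue). Dimensionless
SEIR/SIR ODE integrators are included for like-for-like comparison.

The interplay of the two delays can make the infectious curve *undulate*.
Linearizing around `s ≈ 1` with the ansatz `m ≈ A e^{(α+iω)τ} + B e^{βτ}`
gives a transcendental characteristic equation whose `α ≈ 0` oscillatory
branch reduces to a sinc condition, `sin(ωτ_I)/(ωτ_I) = −1/(2R₀τ_I)`. It has
solutions only when `1/(2R₀τ_I)` is below `γ₀ ≈ 0.2172`, the magnitude of the
global minimum of `sin(x)/x` — hence an analytic onset threshold

```
τ_I^(c) = 1 / (2 γ₀ R₀)        (≈ 1.151 at R₀ = 2)
```

below which no self-excited oscillations occur (and none ever occur for
`τ_I = 0`). The real branch gives the initial growth exponent `β` from
`R₀ = β e^{βτ_I} / (1 − e^{−β})`.

## Worked example

```sh
delayepi simulate --model nrde --r0 2.5 --tau-i 1.0 --s0 0.995 \
    --horizon 60 --step 0.01 --out run.csv
```

writes `run.csv` (columns `tau,m,s,e,i,r`, 6001 rows) and `run.metrics.json`:

```json
{
  "epsilon": 0.0005,
  "i_peak": 0.1590867209,
  "r_inf": 0.8933768563,
  "tau_d": 17.25422112,
  "tau_peak": 8.48,
  ...
}
```

Reading: the epidemic peaks at 15.9% of the population infectious at once,
8.5 recovery times after seeding; it falls below the endemic cutoff
ε = 0.0005 at τ_D ≈ 17.3; in total 89.3% get infected — the same `r_∞` the
classical final-size relation `s_∞ = s₀ e^{−R₀(1−s_∞)}` predicts, and the
same value an SEIR run gives (final size is model- and `τ_I`-independent).

```sh
delayepi oscillations --r0 2.0 --tau-i 1.4
```

```json
{
  "beta_exp": 0.3677771988,
  "omegas": [2.797133755, 3.661820088],
  "oscillatory": true,
  "tau_i_critical": 1.150834712,
  ...
}
```

Reading: at `R₀ = 2`, `τ_I = 1.4` is above the threshold 1.151, so the
infectious curve carries genuine undulations; the `α ≈ 0` analysis brackets
the mode between ω ≈ 2.80 and 3.66 (the exact complex root, via
`delayepi.refine_mode`, is ω ≈ 3.32 — matching the ripple spacing seen in
simulation), and the underlying exponential grows like `e^{0.368 τ}`.

There is also `delayepi sweep` for tabulating `r_inf`, `tau_d` and peak
statistics over parameter grids, and a `--config run.yaml` option mirroring
all flags (keys `r0, tau_i, s0, epsilon, horizon, step`; flags win).

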