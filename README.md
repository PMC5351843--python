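# prodshift

Productivity-driver analysis for fish stock-recruit time series: fit Ricker
models with perturbation, climate, and species-interaction covariates by
maximum likelihood, compare competing hypotheses with AICc, and translate
fitted coefficients into effect sizes — with a synthetic-data generator so
the whole pipeline is testable end to end.

## Who this is for

Fisheries and quantitative-ecology analysts asking *what drove a change in a
population's productivity*: was a decline in recruits-per-spawner density
dependence, a one-off perturbation such as an oil spill, shifting
environmental conditions, or competition and predation from other species?
The motivating system is Pacific herring and wild salmon in Prince William
Sound, Alaska, where the 1989 *Exxon Valdez* spill is temporally confounded
with a climate regime shift, a hatchery-production boom, and recovering
predator populations — but the machinery applies to any brood-year table of
spawners and recruits plus candidate driver series.

## The model

Productivity is recruits per spawner on the log scale. Each candidate model
is a linearised Ricker stock-recruit relationship,

```
log(R/S)_t = a + b S_t + c X_t + v_t,      v_t ~ Normal(0, σ)
```

where `a` is maximum per-capita log productivity, `b` (negative under
density dependence) is the effect of spawner abundance `S_t`, `X_t` is at
most one driver covariate per candidate with coefficient `c`, and `v_t` is
Gaussian residual error. Covariate families:

- **perturbations** — pulse, press, and pulse-with-linear-20-year-recovery
  shapes for an event year (default 1989), at lags 0–2 so the impact lands
  on the brood year whose juveniles were exposed;
- **seasonal climate indices** — means of monthly SST/upwelling series over
  windows that may cross the calendar boundary (Nov–Mar, Oct–Mar, …),
  shifted onto the brood-year axis;
- **lagged annual proxies** — hatchery releases, adult returns, predator
  abundance, indexed so the value at brood year `b` is the calendar-year
  `b + lag` value.

Models are fitted by maximum likelihood (closed-form least squares for this
Gaussian linear class; several populations can share `c` and `σ` while
keeping population-specific `a_i` and optionally `b_i`), compared with

```
AICc = -2 logL + 2k + 2k(k+1)/(n - k - 1)
```

on identical observations, and summarised as ΔAICc tables with support
flags. Effect sizes are reported as the ratio of perturbed to status-quo
mean log-productivity for a fractional increase in a driver:
`(P + c·f·M)/P` for baseline `P`, driver mean `M`, and fraction `f`.

## Worked example

`examples/04_hypothesis_suite.py` simulates 31 brood years (1981–2011) of a
population whose productivity truly responds to an autocorrelated
environmental driver (`c = -0.6`, `σ = 0.4`), then ranks five candidate
hypotheses on identical data:

```
          label      family     loglik  k  n      aicc  delta_aicc  supported
           null        null -31.890881  2 31 68.210334   21.492956      False
       ricker_b     density -29.657945  3 31 66.204779   19.487402      False
evos_press_lag0        evos -28.731551  4 31 67.001564   20.284187      False
evos_pulse_lag0        evos -28.420759  4 31 66.379979   19.662602      False
         driver environment -18.589458  4 31 46.717377    0.000000       True

Best model: 'driver'.
```

The generating model wins by ~19 AICc units; the spill-perturbation shapes,
though temporally confounded with the simulated decline, are not supported.
`examples/03_fit_ricker_model.py` shows the underlying fit — e.g.
`c est -0.51, 95% CI [-0.74, -0.29]` against a truth of `-0.5` — and
`examples/05_effect_size_and_diagnostics.py` prints the effect-size summary:
a 10% increase in a driver with mean 2.5e7 and source-scale coefficient
-2.1576e-8 moves a baseline mean log-productivity of 0.87 to **0.938** of
the status quo.

Each script in `examples/` is a narrative for one capability: reading brood
tables, building perturbation covariates, fitting, model selection, effect
sizes/diagnostics, and Monte-Carlo parameter recovery.

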