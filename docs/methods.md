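# Methods

## Model and estimation

Every candidate is a Gaussian linear model for log recruits-per-spawner,

    log(R/S)_t = a + b S_t + c X_t + v_t,     v_t ~ Normal(0, σ),

the linearised Ricker stock-recruit relationship augmented with at most one
driver covariate per candidate. Because the model is linear with Gaussian
errors and has no latent states, direct maximisation of the likelihood
coincides with ordinary least squares for the regression coefficients and
the divide-by-n residual variance for σ; the engine therefore solves the
weighted normal equations (via a QR least-squares solve) rather than running
an iterative optimiser or a state-space filter. Observation- versus
process-error partitioning is deliberately not modelled.

Joint multi-population fits stack the per-population design blocks:
population-specific intercepts `a_i` always; density dependence either as a
single shared `b` or per-population `b_i`; one covariate coefficient `c`
shared across populations. The residual variance structure is a
configuration switch:

- `sigma_structure="shared"` (default): one σ across populations, closed
  form. This is the most parsimonious reading and keeps the parameter count
  low at short series lengths.
- `sigma_structure="per_population"`: block-specific σ_i estimated by
  iterated feasible GLS (alternate a weighted least-squares solve for the
  coefficients with per-block ML variance updates). Each step increases the
  joint likelihood, so the iteration converges to the joint MLE for this
  block-diagonal structure; convergence tolerance 1e-12 on both coefficient
  and σ updates, cap 200 iterations (typically < 10).

Unbalanced panels are supported: a year missing in one population simply
contributes no row for that population.

Parameter counting (`k_params`) is explicit so AICc is auditable: each
`a_i`, each `b` (one, or one per population), `c` if present, plus one σ (or
one per population). Fits with residual sd below 1e-12 (e.g. noise-free
interpolation) are returned flagged `degenerate` with an undefined
log-likelihood rather than an unbounded one, and the selection layer
excludes them with a warning.

Confidence intervals are Wald intervals built from the residual-degrees-of-
freedom variance estimate and a Student-t quantile. For this model class
that construction has exact finite-sample coverage (it is what standard
linear-model software reports) and agrees with the inverse information
matrix asymptotically; a plain large-sample normal interval with the ML σ
undercovers noticeably at 31 observations.

## Covariates

**Perturbation shapes.** Pulse: 1 in the affected brood year, 0 elsewhere.
Press: a unit step from the affected year onward (equivalently the running
maximum of the pulse — tested as a property). Pulse-recovery: 1 at the
affected year, declining *linearly* to 0 over a configurable recovery span
(default 20 years), 0 after. The linear form is the simplest shape
consistent with a gradual recovery; nothing downstream depends on its exact
curvature and the span is a parameter. Lag semantics: lag k moves the
affected brood year back k years, so the cohort exposed at ocean entry
carries the impact (lag 2 for species entering the ocean as two-year-olds).

**Seasonal indices.** Arithmetic mean of a monthly series over an inclusive
month window; windows crossing December (Nov–Mar, Oct–Mar) are labelled by
the year in which they end, which places "winter immediately before
spawning" in the spawning year. A lag then maps assignment year `b + lag`
onto brood year `b` (negative lags look back, e.g. "winter one year before
spawning" is lag −1). Any month missing inside a requested window is a hard
error naming the gap — silent gap-filling would quietly change an index;
windows running off the ends of the series are skipped instead.

**Annual proxies.** Hatchery releases, adult returns, and predator
abundance enter through a pure re-indexing: brood year `b` takes the source
value of calendar year `b + lag`, because events `lag` years after spawning
act on that cohort (releases of 1981 compete with the 1980 brood at age 1).
Lags compose additively (property-tested).

**Standardisation.** Covariates are z-scored (sample sd, denominator n−1)
over exactly the years entering a fit, by default, inside the suite runner.
This is presentation/conditioning only: the ΔAICc table and all fitted
values are invariant to affine covariate rescaling (tested to 1e-6), and
the effect-size layer back-transforms standardized coefficients by dividing
by the covariate sd.

## Model selection

AICc throughout (`aic()` exists for comparison). The suite runner refits
every candidate on the intersection of years for which the response,
spawners, and *every* candidate's covariate exist — information criteria
are meaningless across differing data, so this restriction is enforced with
a hard error for externally supplied fits with mixed n.

Support rule: the default flags models within one unit of the best model's
maximised log-likelihood (`delta_loglik <= 1`); `delta_aicc <= 2` is
available as an alternative switch, since the two conventions disagree for
models of unequal complexity. Ties for the minimum AICc (within 1e-9) are
broken by fewer parameters, then label order; runner-up rows are flagged
`tied_best`.

`table1_candidates(species)` encodes the per-species candidate rosters of
the motivating Prince William Sound analysis (herring 25, pink 26, Chinook
23, sockeye 21 candidates), including which spill lags exist per species
(no lag-1 for Chinook and sockeye, which enter the ocean in their second
year) and the herring-only humpback-whale covariate. Sockeye covariate
candidates use population-specific density dependence, following the
original analysis.

## Effect sizes and diagnostics

The effect-size summary for a fractional driver increase is reconstructed
from its verbal definition (no closed formula is conventional): a fraction
`f` increase of a driver at mean level `M` adds `c·f·M` to mean
log-productivity `P`, and the summary is the ratio `(P + c·f·M)/P`. It is 1
exactly at `c = 0` and linear in `f` (tested). The baseline `P` for a
multi-population fit is the pooled mean of all usable log(R/S) values by
default; a population-weighted mean (equal weight per population) is a
flag, since either reading of "mean across populations" is defensible.

`predicted_productivity` returns fitted values and `R² = 1 − SS_res/SS_tot`
on the log scale; `residuals_vs_series` regresses model residuals on an
external annual series and reports the trend slope with its standard error —
the screening diagnostic for a driver the current model fails to absorb.

## Synthetic data

The generator inverts the model: `R_t = S_t exp(a + b S_t + c X_t + v_t)`.

Defaults emulate the study conditions: 31 brood years (1981–2011), residual
sd σ = 0.4 (the scale of the fitted salmon/herring series), `a = 1.5`,
`b = −2e−4` on a spawner scale of ~2000 (so density dependence moves
log-productivity by order 0.4 across the observed spawner range). The
driver is a stationary AR(1) with ρ = 0.5 and unit stationary variance
(climate-index-like persistence), drawn with a 100-step burn-in; a supplied
deterministic series (e.g. a spill pulse) can replace it.

Spawners default to a *fixed deterministic* trajectory — a smooth bump
peaking near 1988 over a baseline (rise through the 1980s, decline in the
1990s) — so that spawner abundance is temporally confounded with any
1989-era perturbation covariate, which is precisely the inferential
difficulty of the real system; a lognormal-random-walk option provides
unconfounded spawners for independence checks. Recruits do not feed back
into future spawners (matching the regression framing); a closed-loop
option exists for realism experiments and is excluded from validation runs.

Randomness follows one root `SeedSequence`; per-population and
per-replicate streams are spawned from it, so identical seeds reproduce
byte-identical output and adding a population or replicate never perturbs
existing draws.

`recovery_experiment` is the validation surface: per replicate it
simulates, fits the generating model, records estimates and CI coverage,
and (optionally) runs a candidate suite and records the ΔAICc = 0 winner.
Replicates with degenerate fits are dropped and counted; an experiment with
more than 5% degenerate replicates is flagged unreliable.

## Validation scales and numerical choices

The shipped validation runs use: 100 random fixtures for the
closed-form-oracle equivalence (agreement to 1e-8, observed ~1e-14); 500
replicates at n = 31, σ = 0.4 for CI coverage (binomial noise ±1% around
the nominal 95%); 200 replicates for the n = 1000 bias check (|bias(c)|
observed ≪ 0.05σ) and for each of the selection power (|c|/σ = 1.5,
observed ~100%) and null false-selection (observed ~10%, guard ≤ 25%)
rates. These sizes make the full suite run in well under a minute while
keeping Monte-Carlo noise far from the guard thresholds.

Rank deficiency is detected at tolerance 1e-10 (scaled by the design's
magnitude) before solving; collinear designs raise rather than returning a
pseudo-inverse fit whose coefficients are not interpretable.

## Limitations

- Errors are iid Gaussian within population: no autocorrelated residuals,
  no time-varying coefficients, no observation-error partitioning. These
  are out of scope by design.
- One covariate per candidate: the hypothesis-comparison framing, not a
  general regression builder.
- Passing synthetic-data tests demonstrates correctness of the estimator
  and selection machinery under the model's own assumptions; real brood
  tables carry assessment-model estimation error in both R and S, age-
  structured return schedules, and non-Gaussian recruitment failures that
  the generator intentionally does not emulate.
- The per-species candidate rosters reproduce the motivating analysis's
  non-blank candidate pattern; the original study does not document a rule
  for every omission, so the rosters are data, not logic.
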