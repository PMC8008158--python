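# Methods

This note records the model as implemented, the defaults and why they
were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want to know.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model

One fit concerns one population: a division (country or subnational
area) crossed with a union status (in-union `Y` / not-in-union `N`),
women aged 15–49 collapsed into a single age group.  On an annual grid
the latent state is

- total contraceptive use `P_t = P̃·σ(ρ_P (t−Ω_P) + ε_P,t)`,
- modern share of use `R_t = R̃·σ(ρ_R (t−Ω_R) + ε_R,t)`,
- unmet need `Z_t = (1−P_t)·σ(α + β P_t + ε_Z,t)`,

with `σ` the inverse logit.  Derived: modern use `M = P R`, traditional
use `T = P(1−R)`; by construction `M+T = P` (to one ulp) and
`M+T+Z < 1`, so every draw is a coherent composition of the population.
The logistic systematic curves encode the stylized S-shaped uptake of
contraception; the distortions `ε` are zero-mean *stationary* AR(1)
series (first element `N(0, σ²)`, innovations `σ²(1−ρ²)`), giving
smooth year-to-year departures with marginal SD `σ` at every lag.
Writing unmet need as a logit fraction of non-use, increasing in `P`
through a fixed slope `β`, keeps `Z` inside its logical bound `1−P`
while letting demand rise with use.

Everything that a hierarchical multi-country run would estimate above
the population level is fixed in the `GlobalParameters` fixture: Normal
prior moments for the seven population-level parameters per prior-level
key, the AR(1) pairs `(ρ, σ)` per component, `β`, source-type biases
and non-sampling SDs `τ`, and the extra SD for sample-population
mismatches.  The prior-level key is the division's subregion; in
subnational mode the divisions table lists each subnation as a
"country" whose subregion column holds its parent nation, so the same
lookup yields country-level priors.

### Observation model

A survey with reference time `t_i` (midpoint of fieldwork, mapped to
the nearest grid year, ties rounding down) contributes one Normal term
per non-missing component on the logit scale, with mean
`logit(latent) + bias[s,k]` and variance
`(se/(y(1−y)))² + τ[s,k]² + 1{mismatch}·τ_mm²`.  The delta-method
factor is evaluated at the observed proportion (clamped into
`[0.001, 0.999]`; clamping is recorded per observation in the
processed-data table).  Cross-component error correlations are set to
zero; this diagonal likelihood is a deliberate simplification.
Missing sampling errors are imputed before fitting: per component, the
maximum observed SE in the population's data, else 0.025; all SEs are
floored at 0.005 so no survey claims implausible precision.  The
imputation pools across source types (the data are usually too sparse
to stratify further).

## Inference

The posterior is sampled by Hamiltonian Monte Carlo on the
unconstrained vector (logit asymptotes, log paces, raw timings and
`α`, plus the three `ε` series — dimension `7 + 3·n_years`), using the
exact analytic gradient of the log-posterior.  Details:

- leapfrog trajectories of 9–15 steps (length jittered per iteration),
  dual-averaging step-size adaptation targeting 0.85 acceptance;
- a diagonal mass matrix *initialized at the prior marginal variances*
  (the parameters span four orders of magnitude — timing years vs
  distortions — and starting adaptation from the right geometry is what
  makes short warmups reliable), then re-estimated from the middle 50%
  of warmup with Stan-style shrinkage;
- initialization at the prior means with jitter of 0.1 prior SD, up to
  10 re-jitters if the posterior is non-finite; numerically degenerate
  points (underflowing latents, overflowing paces) evaluate to −∞ and
  are rejected;
- chains run sequentially with RNG streams spawned from the fit seed,
  so identical inputs and seed reproduce draws bit-for-bit.

Defaults are 4 chains × (1000 warmup + 1000 kept).  Zero observations
is legal and samples the prior — used both as a fallback and as a
correctness check.  Convergence diagnostics (split-chain R-hat and ESS
via arviz) are computed for the seven top-level parameters; the
convergence flag requires every finite R-hat < 1.1, and constant
(degenerate) chains report NaN rather than failing.

## Post-processing

Indicators are computed **per draw** and only then summarized:
`total_use = M+T`, `non_use = 1−P`, `total_demand = P+Z`,
`demand_satisfied = P/(P+Z)`, `demand_satisfied_modern = M/(P+Z)`,
`unmet_need_modern = Z+T` (unmet need for modern methods: traditional
users plus women with unmet need), `no_need = 1−P−Z`, and user counts
as proportion × women.  Ratios of quantiles are never used.  Quantiles
are type-7 (linear interpolation between order statistics, numpy's
default), fixed for reproducibility; the default probabilities
(0.025, 0.10, 0.50, 0.90, 0.975) give the median and the 80%/95%
bands.  Population counts are treated as known, matched to the exact
calendar year; a missing year is an error, never an extrapolation.

Aggregation (all-women combination across union statuses, and
multi-population aggregates) takes population-weighted means of the
base proportions per draw and per year, pairing draws by
(chain, iteration) index; fits with different grids or draw counts are
rejected rather than resampled, to avoid silently breaking posterior
dependence.  User counts sum; ratio indicators are recomputed from the
aggregated bases.  Aggregation therefore composes (it is associative
to floating tolerance) and an aggregate of one population is that
population.

## Synthetic data

`generate_global_parameters` produces a documented stand-in for a
global-run fixture: total-use asymptote prior centred at logit 0.5
(≈62%) with SD 1, paces log-centred at 8%/yr (total use) and 6%/yr
(modern share) with SD 0.4, inflection years 2000 and 1995 with SD 8,
unmet-need level `α ~ N(−1, 0.5)`, `β = 1`, AR(1) autocorrelations
drawn in [0.8, 0.95] with marginal SDs in [0.05, 0.15], DHS biases
exactly zero and other source biases `N(0, 0.05)`, non-sampling SDs in
[0.02, 0.10], mismatch SD 0.1.  These are demographically plausible
magnitudes chosen once; they are constants of this package, not claims
about any published estimates.

`simulate_population` draws the population parameters from those
priors, builds the latent trajectories through the model's own
equations, and defaults to 5 surveys across a 25-year grid (1990–2014)
with mixed source types and proportion-scale SEs of 0.02 — the data
sparsity typical of a single-country series.

One subtlety matters for calibration.  Because the likelihood evaluates
the delta-method SE at the *observed* proportion, the observation model
is not "Normal noise with variance fixed at the latent value": drawing
data that way measurably breaks self-simulation coverage (observations
that randomly land where the variance function is small get too much
weight, biasing the fit).  The simulator therefore draws `logit(y)`
from the *normalized observation density itself* — the likelihood's
exact form — by numerical inverse-CDF sampling.  This density has a
Gaussian core but heavy (asymptotically exponential) tails: extreme
observed proportions imply enormous variance, so their quadratic
penalty flattens.  A nontrivial fraction of simulated observations is
consequently far from the latent value and nearly uninformative — a
property of the model itself, which discounts them symmetrically.
Component triplets are redrawn jointly until they satisfy the
survey-data invariants (component sums ≤ 1), so every simulated
dataset is readable by construction; this conditioning removes a small,
parameter-dependent slice of probability and is the remaining (minor)
approximation in self-simulation checks.

What a green calibration test establishes: that sampler, likelihood,
priors and post-processing are mutually consistent on data from the
model's own stated world.  What it does not establish: robustness to
real-data features the generator does not emulate — age structure,
survey-design effects beyond a scalar SE, correlated component errors,
informative survey timing, or model misspecification of any kind.

## Known limitations

- The diagonal observation likelihood ignores the correlation between
  modern and traditional use errors within one survey.
- `β` (the unmet-need slope on total use) is fixed by the fixture, not
  estimated.
- Counts are exact inputs; their uncertainty is not propagated.
- The sampler is single-process; chains run sequentially.
- Subnational mode reuses the national machinery with a re-keyed
  fixture; no spatial pooling across subnations is attempted.
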