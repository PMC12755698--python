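# Methods

## The analysis

`heatsynergy` implements a warm-season (June–September) case-crossover
analysis of the joint short-term effects of heat and fine particulate matter
on heat-related hospitalization. Each hospitalized person contributes one
*case day* (the admission date of their first event over the study period)
and up to four *referent days*: every other day in the same calendar month
and year sharing the case day's day of week. Because exposure is compared
within person and within month, all time-invariant personal characteristics
and any confounder that is constant over the month are conditioned out of the
likelihood exactly.

Exposures attached to each person-day are the daily maximum temperature on
that day (`temp_window_days = 1`) and the mean PM2.5 over the day and the two
preceding days (`pm_window_days = 3`); a day only enters the analysis when
its full window is covered by the area's series. Person-days whose 3-day
PM2.5 exceeds the pooled (case + referent) 95th percentile are excluded
before fitting; a matched set whose case day is excluded is dropped entirely,
because a stratum without its case contributes nothing to the conditional
likelihood. The trimming quantile is configurable (0.99 for the sensitivity
analysis) and the computed threshold is recorded in the run manifest.

The model is a Bayesian analogue of conditional logistic regression. For
stratum *s* with design rows `x_1 … x_m` and case row `c`,

    log L_s(β) = x_c·β − log Σ_j exp(x_j·β).

The design has three blocks: a natural cubic spline in temperature (default
4 df), a natural cubic spline in 3-day PM2.5 (default 4 df), and an
interaction — either the raw product `T·P` (primary model; °C·µg/m³ units,
so the exponentiated coefficient is the multiplicative interaction OR per
1 °C·µg/m³) or a tensor-product spline surface (sensitivity model). No
intercept is included; conditioning absorbs it.

Effects are summarized from posterior draws at contrast levels taken from
the **case-day** exposure distributions — medians `(t0, p0)` as reference
and 95th percentiles `(t1, p1)` as comparison:

* `OR10 = OR(t1, p0)`, `OR01 = OR(t0, p1)`, `OR11 = OR(t1, p1)`, each
  relative to `(t0, p0)`;
* the additive-scale relative excess risk due to interaction,
  `RERI = OR11 − OR10 − OR01 + 1`, positive under synergism. Because the
  outcome is rare, this odds-ratio form approximates the risk-ratio RERI.

The RERI is reported two ways: the *per-draw* summary (posterior mean and
95% equal-tailed interval of the RERI computed within each draw) and the
*plug-in* of the three posterior-mean ORs. Because the RERI is linear in
the ORs, the two point estimates coincide exactly; only the per-draw
computation yields a valid credible interval, which is why both are emitted
and labeled.

## Spline basis

The natural cubic basis is the standard truncated-power construction: with
knots `k_1 < … < k_K` (interior plus two boundary knots), the columns are
`N_1(x) = x` and `N_{j+1}(x) = d_j(x) − d_{K−1}(x)`,
`d_j(x) = [(x−k_j)_+³ − (x−k_K)_+³]/(k_K − k_j)`. Every column is exactly
linear beyond the boundary knots, so the span contains all linear functions
(which makes the interaction fit invariant to centering the product term, a
property the tests verify) and extrapolation is linear by construction
(flagged with a warning). Interior knots default to equally spaced quantiles
of the **case-day** exposures; boundary knots to the min/max of the trimmed
analysis values. `df = 4` per exposure is the smallest value that leaves
visible curvature in the fitted exposure-response curves; it is configurable
and no automatic selection is attempted. The tests cross-check the basis
against patsy's independent cubic-regression-spline implementation by
comparing fitted values on a shared knot set.

For the tensor sensitivity model the design is
`[NCS(T) | NCS(P) | NCS(T) ⊗ NCS(P)]`: the marginal spline blocks are kept
and the single product column is replaced by the row-wise outer product of
two marginal natural bases (default 4 × 4 = 16 interaction columns). This
column space equals the full bivariate natural-spline surface basis; an
interaction-only tensor block without marginal blocks cannot represent main
effects, since the no-intercept marginal spans exclude constants.

## Estimation

**Maximum likelihood.** A damped Newton ascent on the exact conditional
log-likelihood with analytic gradient and Hessian (the log-likelihood is
concave; the line search never accepts a decrease). Convergence requires
gradient max-norm ≤ 1e−8 (1e−6 is enforced as a hard floor). Diverging
coefficients without convergence raise an explicit separation error; a
rank-deficient within-stratum design is reported as non-identifiable. The
covariance is the inverse observed information. The MLE doubles as the
deterministic oracle for the sampler and is validated against an independent
reference implementation in the tests.

**Posterior sampling.** Priors are independent normal(0, 5²) per coefficient
(weakly informative at the scale of log-odds per °C or per µg/m³; a flat
prior is available for oracle comparisons). Sampling uses an ensemble MCMC
sampler (emcee) with a differential-evolution move mixture (80% DE, 20%
DE-snooker), chosen over the default stretch move after it showed several-fold
better mixing on this target. Two numerical choices matter:

* *Preconditioning*: sampling runs in the Laplace-standardized space
  `β = β̂ + L z` with `L` the Cholesky factor of the inverse observed
  information at the MLE, so the target is near-spherical regardless of the
  raw coefficient scales (which span orders of magnitude between spline and
  product-term columns).
* *Ensemble shape*: `max(4p + 4, 16)` walkers, 1000 warmup steps and at
  least 1000 retained steps (so that per-walker chains are long enough for a
  stable split-R̂); walkers start in a 0.1-SD ball around the MLE.

Diagnostics are computed with arviz after grouping walkers into four
pseudo-chains: rank-normalized split-R̂ must be < 1.01 and bulk ESS > 400
for every coefficient, otherwise the fit is rejected with a diagnostic
report. Because ensemble walkers interact, grouped pseudo-chains are not
independent chains; the thresholds are enforced on this grouped statistic,
which in practice is the stricter reading. All likelihood code uses the
max-shifted logsumexp; there is no stratum-size limit.

## The synthetic data generator

Real claims and exposure-surface data for this design are access-restricted,
so the package ships a fully specified data-generating process whose truth
is computable in closed form.

*Temperature* (°C): a seasonal sinusoid (baseline 24.417 °C, amplitude
6.0 °C, peak at day-of-year 197) plus stationary AR(1) deviations with
marginal SD 4.847 °C and lag-1 correlation 0.7 (so that 3-day windows differ
from single days in a realistic way). These values were calibrated once so
the pooled warm-season daily maximum has mean ≈ 29.2 °C and SD ≈ 5.0 °C.

*PM2.5* (µg/m³): lognormal with log-mean 2.059 and log-SD 0.72, the log
innovation correlated at 0.30 with the same-day standardized temperature
deviation. The correlation magnitude is a free choice (observational studies
report the two exposures as "often correlated" without a figure); 0.30 gives
a clearly positive but not deterministic dependence. The scale and shape
were calibrated once so the 3-day mean, after 95th-percentile trimming, has
mean ≈ 9.4 µg/m³ and SD ≈ 3.7 µg/m³, with the heavy right tail that makes
trimming consequential.

*Events*: each person is assigned uniformly to an area; on every covered
day an event occurs with probability `expit(α + β_T·T + β_P·P + β_TP·T·P)`
evaluated at the **windowed** exposures — the same quantities the analysis
model uses, so the conditional logistic model is correctly specified under
the linear DGP and parameter recovery can be tested exactly. Only each
person's first event is kept, mirroring the first-hospitalization rule. A
hazard with median daily probability ≥ 0.5 triggers a warning because the
rare-outcome approximation behind the OR-based RERI then degrades. The
default coefficients (α = −6.6, β_T = 0.0029, β_P = −0.009,
β_TP = 3.4e−4) are sized so the true effects at the default contrasts match
the magnitudes this literature reports — OR ≈ 1.05 for the temperature
contrast, ≈ 1.01 for PM2.5, RERI ≈ 0.03, multiplicative interaction OR
≈ 1.0003 — including a slightly protective PM2.5 association on cool days
(negative main effect, positive interaction). `true_effects` returns the
closed-form ORs and RERI for any hazard and contrast; the baseline α cancels.

What the generator does **not** emulate: spatial correlation between areas,
grid-to-area exposure aggregation error, demographic covariate effects,
seasonal confounding structure beyond the sinusoid, measurement error, and
event dependence between persons. Passing tests therefore demonstrate that
the estimation machinery recovers known truth under a correctly specified
rare-event mechanism — not that the design is robust to those real-data
complications, which the matched structure is *designed* to absorb but which
the simulation cannot probe.

## Problem sizes and defaults

The default study (`RunConfig()`) simulates 25 areas over one warm season
(2016-05-30 to 2016-09-30, the two lead-in days covering the 3-day window on
June 1) and 20,000 persons, yielding roughly 3,000–3,500 matched sets — a
deliberate scale-down from a national claims study (~113,000 cases) chosen
so a full run completes in about a minute on one core. At this size the
credible intervals around weak true effects (RERI ≈ 0.02) are wide; the
point estimates are unbiased but a single run cannot "detect" the
interaction, exactly as a small study could not. Parameter-recovery tests
instead use a stronger hazard (β_T = 0.05, β_P = 0.02, β_TP = 0.003) at
~2,000 strata, and calibration is checked over 100 replicates of a
zero-effect DGP at ~500 strata.

Other defaults: trim quantile 0.95; contrast quantiles (0.5, 0.95); prior
scale 5; 4,000 minimum retained draws; seed 0. Every run derives its three
stage seeds (exposures, events, sampler) from the config seed via
`SeedSequence.spawn`, and identical configs produce byte-identical bundles.

## Known limitations

* The conditional likelihood requires exactly one case per stratum; matched
  sets that lose their case (to coverage or trimming) are dropped and
  logged, never silently imputed.
* The first-event rule induces a slight depletion of high-hazard persons
  late in the season; at the default event rates the induced bias is far
  below sampling noise, but it is a real approximation.
* Ensemble-MCMC diagnostics on grouped walkers are not identical to
  multi-chain R̂; see above.
* Referent days after a person's death are not excluded (exposure, not
  survival, defines referent validity in time-stratified designs); the
  generator has no mortality process, so the choice is untestable here and
  is simply recorded.
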