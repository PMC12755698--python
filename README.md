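# heatsynergy

Case-crossover analysis of the independent and synergistic short-term
effects of heat and fine particulate matter (PM2.5) on heat-related
hospitalization, built for environmental epidemiologists who want a tested,
reproducible pipeline: time-stratified referent selection, exposure
windowing and percentile trimming, Bayesian conditional logistic regression
with natural cubic spline exposure-response curves, and additive-scale
interaction (RERI) estimation — exercised end to end against a synthetic
data-generating process with computable truth.

## The design and the model

Each hospitalized person contributes their first warm-season
(June–September) admission as the *case day* and, as *referent days*, every
other day of the same calendar month sharing the case day's day of week
(three or four per case, before or after the event). Comparing a person's
exposure on the case day with their own exposure on referent days removes
all time-invariant confounding by construction.

Exposures per person-day are the same-day maximum temperature T (°C) and
the 3-day mean PM2.5 P (µg/m³, the day and two preceding days). Person-days
with P above the pooled 95th percentile are trimmed. The matched-set
(conditional logistic) log-likelihood for stratum *s* with case row *c* is

    log L_s(β) = x_c·β − log Σ_j exp(x_j·β),

with the design

    x = [ ns(T; 4 df) | ns(P; 4 df) | T·P ]

(no intercept; a tensor-product spline surface can replace the product term
as a sensitivity model). Posterior sampling uses independent normal(0, 5²)
priors and ensemble MCMC, gated on split-R̂ < 1.01 and bulk ESS > 400.

Effects are summarized at case-day contrast levels — medians (t₀, p₀) to
95th percentiles (t₁, p₁):

* OR(t₁,p₀), OR(t₀,p₁), OR(t₁,p₁), each vs (t₀, p₀), posterior mean and
  95% equal-tailed credible interval;
* RERI = OR₁₁ − OR₁₀ − OR₀₁ + 1 (additive-scale synergy; per-draw summary
  and plug-in of posterior-mean ORs);
* the multiplicative interaction OR per 1 °C·µg/m³, `exp(β_TP)`.

See `docs/methods.md` for the full model account, the synthetic
data-generating process and its calibration, and numerical choices.

## Worked example

```python
import heatsynergy as hs

results = hs.run_pipeline(hs.RunConfig(seed=1), out_dir="results")
m = results["manifest"]
eff = m["effects"]
print(f"matched sets: {m['n_matched_sets']}, trim threshold {m['trim_threshold']:.2f} ug/m3")
print(f"contrast: T {eff['contrast']['t0']:.1f}->{eff['contrast']['t1']:.1f} C, "
      f"P {eff['contrast']['p0']:.1f}->{eff['contrast']['p1']:.1f} ug/m3")
for k in ("or_temp", "or_pm", "or_joint", "reri"):
    s = eff[k]
    print(f"{k}: {s['mean']:.3f} (95% CI {s['ci_low']:.3f}, {s['ci_high']:.3f})")
print("true RERI under the generator:", round(m["dgp_true_effects"]["reri"], 4))
```

prints (seed 1):

```
matched sets: 3259, trim threshold 19.55 ug/m3
contrast: T 28.9->36.8 C, P 8.8->16.3 ug/m3
or_temp: 1.028 (95% CI 0.900, 1.165)
or_pm: 1.030 (95% CI 0.906, 1.170)
or_joint: 1.030 (95% CI 0.846, 1.243)
reri: -0.028 (95% CI -0.163, 0.115)
true RERI under the generator: 0.0215
```

The default synthetic study simulates ~3,300 cases with true contrast
effects of realistic magnitude (true OR for the temperature contrast 1.05,
for PM2.5 1.01, true RERI 0.02). At this deliberately scaled-down size the
posterior means sit well inside their credible intervals around the truth,
and the intervals are honest about the fact that a study of 3,000 cases
cannot resolve a RERI of a few hundredths — estimates tighten as
`n_persons` grows. The results bundle also contains the exposure-response
OR curves, the OR grid over the (T, P) plane, posterior draws, the cohort
summary and a manifest with knots, thresholds, MCMC diagnostics and an
exact person-day accounting ledger.

The same run is available from the shell:

```bash
heatsynergy run-all --seed 1 --out results      # or stage by stage:
heatsynergy simulate --config cfg.yaml --out results
heatsynergy build-design --config cfg.yaml --out results
heatsynergy fit --config cfg.yaml --out results
heatsynergy effects --config cfg.yaml --out results
```

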