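# avypop — avalanche mortality and mountain ungulate population dynamics

Snow avalanches kill mountain ungulates directly, and unlike most
snow-mediated mortality they remove prime-aged animals — the individuals
that otherwise have the highest survival and drive population growth. This
package implements a complete demographic analysis of that process for
coastal Alaska mountain goat (*Oreamnos americanus*) populations, for
wildlife biologists and quantitative ecologists who want to reproduce,
probe, or extend it:

1. **Survival submodel.** Annual survival of radio-marked animals is a
   binomial GLMM on the logit scale,

   `logit S(stage, m) = β₀ + offset(stage) + β_avy · m + u_ind`,

   where `m` is the proportion of the population killed by avalanches that
   year and `u_ind ~ N(0, σ²)` an individual random intercept (reference
   category: old males). The fitted slope `β_avy = −5.475` implies
   avalanche mortality is largely **additive**: extra avalanche deaths are
   deaths that would not otherwise have happened, except partially at
   rates below the mean.

2. **Proportional survival change factor.**
   `Ŝ_change(stage, m) = S(stage, m) / S(stage, m̄)` with `m̄ = 0.07`
   rescales baseline vital rates under any avalanche scenario; a neonate
   logit line with the same slope handles first-year survival.

3. **Projection model.** A dual-sex, 20-age-class matrix model (annual
   census after recruitment), with age-specific fecundity calibrated so
   deterministic growth at the mean avalanche rate equals the observed
   baseline `λ = 1.015`. Scenario simulations apply the change factors and
   lognormal interannual fecundity variation (SD 0.106) over 2- and
   30-year horizons, 1000 replicates, 100 animals at the stable sex-age
   distribution.

4. **Recovery and recurrence.** Closed-form recovery time
   `t = log(1/(1−d)) / log(λ)` for a decline `d`, and empirical exceedance
   probabilities / recurrence intervals from a 43-year record of
   population-level avalanche mortality (range 0–23%, mean 7%).

Raw telemetry for this species is restricted, so the `synthetic` module
generates known-fate monitoring data with the exact statistical structure
the analysis assumes; every stage of the pipeline is testable offline.

## Worked example

```python
import avypop as ap

fit = ap.reference_fit()                      # published coefficients
ap.predict_survival(fit, "old_male", 0.07)    # 0.6134 -> prints as 0.61
ap.change_factor(fit, "adult_female", 0.23, 0.07)   # 0.858

schedule = ap.calibrate_baseline(fit)         # lambda(0.07) = 1.015
spec = ap.ScenarioSpec(m=0.23, horizon_years=30, n_reps=1000, seed=11)
ap.run_scenario(spec, fit, schedule).mean_lambda    # 0.8491

ap.recovery_time(0.154, 1.015)                # 11.23 years
ap.exceedance(ap.reference_event_series(), 0.23).recurrence_years  # 43.0
```

Interpretation: at the worst observed avalanche year (23% of the
population killed), annual growth falls from 1.015 to ≈ 0.85; the
resulting ~15% single-winter decline takes ≈ 11 years to recover at
baseline growth, while such an event recurs about once in 43 years.

## The analysis, end to end

Numbered drivers under `analysis/` run the study and write tables under
`results/` (run them in order from the repository root):

| script | what it does |
|---|---|
| `01_simulate_known_fates.py` | synthetic monitoring program (421 individuals, 17 y) + 43-year event record |
| `02_fit_survival_model.py` | GLMM fit, compared against the published coefficients |
| `03_survival_response.py` | stage survival & change factors vs. avalanche rate; additivity check |
| `04_scenario_projections.py` | calibrated stochastic projections; 2 y vs 30 y; decline threshold (≈ 8.9%) |
| `05_recovery_recurrence.py` | recovery times, quartile bands, recurrence intervals, the three anchored scenarios |

The same stages are scriptable via the `avypop` CLI
(`synth | fit | calibrate | simulate | threshold | recover | recurrence | all`)
or `avypop.pipeline.run_pipeline`, which writes a manifest (config hash,
seeds) sufficient to reproduce every output byte-for-byte.

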