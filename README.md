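# kratkit

Accelerometry-based behavior classification and diel activity-budget
analysis for small nocturnal mammals.

Field studies of small, secretive, nocturnal rodents (the motivating
case is a < 50 g kangaroo rat carrying a 25 Hz tri-axial accelerometer)
produce two kinds of raw material: multi-day acceleration logs and short
video-validated behavior annotations.  `kratkit` turns these into
classified behavior time series and statistical conclusions, in five
stages:

1. **Features** — traces are tiled into non-overlapping windows of 1–9 s
   and summarized by 16 statistics (41 numbers per window): per-axis
   mean, SD, max, min, percentiles, covariance and Pearson correlation,
   mean vector norm, dynamic body acceleration (DBA) and ODBA
   (mean |DBAx|+|DBAy|+|DBAz|), first-difference statistics, wave
   amplitude and line crossings.
2. **Classification** — classes (motionless, travel, foraging, grooming)
   are balanced down to the rarest class, split 50/50 stratified, and a
   linear SVM, decision tree and random forest are compared across window
   sizes and feature sets; the winner maximizes the mean of macro
   accuracy, precision and recall, and then annotates whole deployments.
3. **Ephemeris** — solar altitude assigns each instant one of eight diel
   light phases (evening, dusk, evening twilight, night, morning
   twilight, dawn, morning, day); lunar geometry supplies the illuminated
   fraction k = (1 + cos i)/2, the low/medium/high moon-intensity
   category (thresholds 0.33/0.66) and a moon up/down flag.
4. **Budgets** — classified windows aggregate into proportions of time
   per behavior by (individual, night, light phase), joined with nightly
   weather and moonlight covariates.
5. **Mixed models** — behavior proportions are modeled by GLMMs with
   crossed random intercepts for individual and night; the response
   family (gaussian/poisson/binomial/gamma) is chosen by AIC, predictors
   are screened with variance inflation factors, fixed effects are tested
   with Wald χ², and fit is summarized by conditional R²
   (Nakagawa-style, family-appropriate residual variance).

Because real deployments are not required to exercise any of this, the
package ships a first-class synthetic generator: behavior bouts from a
phase-switched continuous-time Markov chain with nocturnal defaults,
per-behavior acceleration signatures (with deliberately overlapping
foraging/grooming parameters, so the classifier shows the
foraging↔grooming confusion structure seen in real data), and nightly
covariates — all with recorded ground truth.

See `docs/methods.md` for the modeling details and conventions.

## Worked example

```python
from datetime import datetime, timezone
from kratkit import synth, features, classify, ephemeris

site = ephemeris.SiteContext(30.2, -103.5, "America/Chicago")

# three synthetic 14 h deployments with known per-sample behavior labels
deps = [synth.simulate_deployment(f"kr{i:02d}",
                                  datetime(2021, 6, 1 + i, 18, tzinfo=timezone.utc),
                                  14.0, site, seed=100 + i)
        for i in range(3)]

# labeled 6 s feature tables, model grid, selection
import pandas as pd
tables = {}
for w in (2.0, 6.0):
    tables[w] = pd.concat(
        [features.feature_table(d.trace, w,
             annotations=synth.schedule_to_annotations(d.individual_id, d.schedule))
         for d in deps], ignore_index=True)
result = classify.model_selection(tables, seed=0)
best = result.best
print(best.spec.label(), round(best.overall_accuracy, 3))
print(best.confusion)
```

prints

```
random_forest/reduced/6s 0.974
[[486   0   0   0]
 [  0 486   0   0]
 [  0   0 462  24]
 [  0   0  27 459]]
```

— the random forest at a 6 s window wins; motionless and travel are
nearly perfect, and essentially all remaining error is the
foraging↔grooming pair (rows/columns in the order motionless, travel,
foraging, grooming), the same confusion structure reported for real
kangaroo-rat data.  Fitting a moonlight/weather model on budget data with
a known humidity effect:

```python
from kratkit import mixed
data, truth = synth.simulate_budget_dataset(14, 20, beta_humidity=0.8, seed=3)
fit = mixed.fit_mixed("proportion ~ humidity_z", data,
                      family="binomial", weights="n_total")
print(fit.summary())
```

```
Mixed GLM (Laplace ML)
  family: binomial   n_obs: 280   converged: True
  logLik: -765.456   AIC: 1538.912   conditional R2: 0.189

  term                              coef        se       z
  Intercept                      -1.0543    0.1478   -7.13
  humidity_z                      0.6300    0.1082    5.82

  random intercept individual: var 0.1420
  random intercept night: var 0.2265
```

The injected slope (0.8) is recovered within sampling error and is
strongly significant by the Wald χ² test.

There is also a CLI mirroring the stages
(`kratkit simulate|features|train|annotate|ephemeris|budget|model|run-all`),
each taking `--config <yaml>` and `--seed`; `run-all` chains everything
into one output directory with a reproducible manifest.

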