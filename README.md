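# avitrend

Hierarchical Bayesian density–habitat modeling for avian point-count data:
a combined distance-sampling + removal-model observation process, a
zero-inflated Poisson abundance model with a 2-D suitability spline,
continuous scale-of-effect (buffer radius) selection for landscape
covariates, region-level random population trends, and the downstream
products — trend classification, percent annual change, and density
prediction surfaces with QA masks.

Real monitoring data for this model family are restricted, so the package
ships a first-class synthetic-data generator (`avitrend.simulate`) that
runs the full generative model forward (explicit simulated individuals
pushed through the availability/detection process), making every stage
testable offline.

## Layout

| module                 | role |
|------------------------|------|
| `avitrend.covariates`  | rasters, buffer-mean summaries at a ladder of radii, scale interpolation, correlation/VIF screens |
| `avitrend.detection`   | removal-model availability, binned half-normal detectability, truncation |
| `avitrend.abundance`   | ZIP abundance likelihood, BCR random-effect prior, suitability spline |
| `avitrend.model`       | data assembly and the marginalized joint log posterior |
| `avitrend.inference`   | adaptive Metropolis-within-Gibbs MCMC, R-hat/ESS, posterior predictive check |
| `avitrend.trends`      | trend classification, density conversion, prediction maps, phase helper |
| `avitrend.simulate`    | synthetic studies (tiny/small/medium fixtures) |
| `avitrend.io` / `cli`  | CSV/ASCII-grid readers and writers, survey-design filters, CLI |

## CLI

All stages share plain-directory interchange (CSV tables, ESRI ASCII-grid
rasters, JSON manifests):

```bash
avitrend simulate --size tiny --seed 7 --out fixtures/tiny
avitrend summarize --rasters fixtures/tiny/rasters --grids grids.csv \
    --radii 0:10000:100 --out stack.csv
avitrend fit --data fixtures/tiny --seed 42 --out fit/
avitrend check --data fixtures/tiny --fit fit/ --out fit_report.json
avitrend classify-trends --fit fit/ --out trends.csv
avitrend predict --data fixtures/tiny --fit fit/ --year 2009 --out maps/
```

`fit` accepts a YAML model config (`--config`) naming the fixed and
scale-selected covariates, the spline dimension `k_spline`, and whether a
survey-level random effect is included; without one, it derives the model
from the study manifest.

## Notes

- Counts may be 5- or 6-minute; the removal model uses the per-survey
  duration.
- Distance truncation uses the type-7 (linear interpolation) 90% quantile;
  detection distances are binned into 10 equal bins inside the likelihood.
- The survey-level random effect is applied on the log scale (lognormal
  overdispersion) so the Poisson mean stays positive.
- MCMC runs 4 chains by default at a desk-scale draw budget
  (2500 warmup + 4000 iterations thinned to 500 retained per chain,
  2000 retained total); production-scale budgets are a config change.
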