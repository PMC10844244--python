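# bopmeta

Conservative evidence synthesis for dichotomous risk factors. `bopmeta` fits a
mixed-effects meta-regression of log relative risk (pooling RR/OR/HR effect
sizes), with:

- **observation harmonization** — CSV tables of extracted effect sizes with
  95% CIs are converted to log space; overlapping observations from one study
  sample get their SEs inflated (`sqrt(k)` per group of `k`) so the sample is
  not over-represented;
- **robust trimming** — least-trimmed-squares exclusion of the most discordant
  10% of observations (only for models with more than 10 data points);
- **bias covariates** — ten binary study-characteristic flags, screened for
  eligibility (two data points per value), selected by a step-wise Lasso path
  with a ridge-refit significance test, and used to adjust observations toward
  gold-standard study designs;
- **heterogeneity-aware uncertainty** — the between-study variance is
  estimated by maximum marginal likelihood; its sampling SD comes from the
  inverse Fisher information, and two 95% uncertainty intervals are reported
  (with and without the heterogeneity component);
- **conservative scoring** — the 5th-quantile risk function closest to the
  null, the signed half-log risk-outcome score, and a 0–5 star evidence
  rating gated on the fixed-effects interval excluding the null;
- **publication-bias diagnostics** — Egger's regression of model residuals on
  total SE, plus modified funnel-plot and forest-plot outputs;
- **synthetic data** — a seeded generator for observation sets with known
  truth (study random effects, covariate shifts, overlap groups, outliers,
  significance-based censoring) used throughout the test suite.

## CLI

```sh
bop simulate --config sim.yaml --out obs.csv   # synthetic observation table
bop validate obs.csv                           # schema/invariant checks
bop fit obs.csv --config run.yaml --seed 1 --out run/
bop grid obs.csv --grid grid.yaml --seed 1     # sensitivity variants x {trim, no-trim}
bop report run/                                # re-render figures for a run
```

`bop fit --out` writes `summary.{json,csv}`, `config_echo.yaml`, forest and
funnel plots (PNG + SVG), and the funnel point table. Run configs, covariate
registries, simulation configs, and grids are YAML; see `RunConfig`,
`bopmeta.covariates.load_registry`, and `bopmeta.simulate.load_config`.

Input CSV schema (header row, one row per effect size):
`obs_id, study_id, measure, effect, ci_lower, ci_upper, overlap_group, sex,
exposure_definition, exposure_temporality, outcome_aggregate, sample_size,
design`, plus one `cv_`-prefixed 0/1 column per bias covariate. Emitted
tables append `log_effect, log_se, raw_log_se`.

## Library sketch

```python
from bopmeta import (read_csv, downweight_overlaps, fit,
                     summarize_heterogeneity, eggers_test, summarize)

obs = downweight_overlaps(read_csv("obs.csv"))
res = fit(obs, trim_fraction=0.10, seed=1)
het = summarize_heterogeneity(obs, res)
row = summarize(res, het, eggers_test(obs, res), outcome="example")
print(row.as_dict())
```
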