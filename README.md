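# stochclock

Tools for quantifying the stochastic component of epigenetic clocks.

The package simulates stochastic DNA-methylation accrual at clock CpGs
(per-step Bernoulli alterations with probability
`p_c = 1 - exp(-gamma * |effect_c|)` and half-normal deviates added in
inverse-normal-quantile space), fits the simulator's two parameters
`(gamma, sigma)` to young/old reference panels by recursive grid
search, trains elastic-net "stochastic clock" analogs on simulated
cohorts, and compares them against ordinary clocks via the RR2 ratio
(squared Pearson correlation of the stochastic clock over that of the
original clock on the same cohort). EAA/IAA age-acceleration residuals
and their phenotype association tests sit on top.

All inputs a real analysis would need (young/old sorted-cell panels,
whole-blood-like cohorts mixing stochastic and nonstochastic aging
signal, immune-cell-fraction matrices) can be generated synthetically,
so the entire pipeline is testable offline.

## Layout

| module | contents |
| --- | --- |
| `stochclock.markov` | two-state Markov chain: transition matrix, closed form, recurrence, steady state, linear approximation |
| `stochclock.effects` | per-CpG ground states / signed effect sizes from young–old groups; CpG filters and top-k selection |
| `stochclock.simulate` | the stochastic accrual engine (quantile-space half-normal drift) |
| `stochclock.fit` | recursive 2-D grid search for `(gamma, sigma)` minimizing end-state MAE |
| `stochclock.clocks` | artificial-cohort generation, elastic-net training with RMSE model selection, clock application |
| `stochclock.evaluate` | MAE / Pearson R / R², RR2 records, the RR2-vs-(1/R²−1) diagnostic, cross-cohort meta-analysis |
| `stochclock.acceleration` | EAA/IAA residuals and Wilcoxon / ordinal-regression association tests |
| `stochclock.synth` | synthetic reference panels, aging cohorts, cell-fraction matrices |
| `stochclock.io` / `stochclock.cli` | TSV/CSV/JSON readers and writers, provenance headers, the `stochclock` CLI |

## CLI

```sh
stochclock synth --n-cpgs 353 --n-young 43 --n-old 11 --seed 1 --out-dir panel/
stochclock fit-params --young panel/young.tsv --old panel/old.tsv --seed 1 --out fit.json
stochclock simulate-cohort --young panel/young.tsv --effects panel/true_effects.csv \
    --gamma 9.25 --sigma 0.0005 --seed 2 --out cohort.tsv --out-ages cohort_samples.csv
stochclock train-clock --train train.tsv train_samples.csv \
    --select select.tsv select_samples.csv --out clock.csv
stochclock apply-clock --clock clock.csv --betas test.tsv --sheet test_samples.csv --out pred.csv
stochclock rr2 --stoc pred_stoc.csv --orig pred_orig.csv --out rr2.json
stochclock accel --predictions pred.csv --sheet samples.csv --phenotype sex --out accel.csv
stochclock meta --ratios ratios.csv --clock-a StocZ --clock-b StocH --out meta.json
stochclock run --seed 1 --out-dir run/       # full synthetic pipeline
```

Every stage accepts `--seed`; outputs carry `#`-prefixed provenance
headers (stage, seed, config hash) that all readers skip.

## Notes

- Simulated beta-values stay inside `(0, 1)` by construction; inputs
  are clipped to `[1e-6, 1 - 1e-6]` before the inverse-normal
  transform (configurable via `SimParams.clip_eps`).
- Clock application standardizes each CpG within the evaluation
  dataset by default (predictions are then invariant to per-CpG affine
  shifts between datasets); pass `standardization="train-frozen"` to
  apply the stored training statistics instead.
- Elastic-net penalties follow scikit-learn's parameterization, so
  lambda values are comparable only within this package; model
  selection is by selection-set RMSE, never by the lambda value itself.
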