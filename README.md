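# mlmcorr

Small-sample corrected standard errors and inference for two-level linear
models on clustered data with heteroscedasticity at either level and
unbalanced cluster sizes.

The package provides:

- **`mlmcorr.synthetic_data`** — a generator for two-level clustered data
  with controlled heteroscedasticity (variance patterns VP1/VP2/VP3 at each
  level, cluster-size-linked variance with a ~5:1 gradient, five-strata
  unbalanced designs) and the full-factorial 864-cell simulation grid.
- **`mlmcorr.lmm_core`** — OLS, random-intercept (RI) and random-slope (RS)
  fits; REML variance components with profiled residual variance and GLS
  fixed effects, exposing the per-cluster design/covariance blocks.
- **`mlmcorr.robust_se`** — cluster-robust covariance estimators CR0, CR1
  and CR2 (bias-reduced linearisation with adjustment matrices) plus
  Satterthwaite estimated degrees of freedom for single-coefficient t tests.
- **`mlmcorr.kr_correction`** — the Kenward-Roger adjusted fixed-effect
  covariance and moment-matched degrees of freedom for REML fits.
- **`mlmcorr.evaluation`** — relative bias of SEs, empirical type I error
  with the liberal-criterion classification (robust within [0.025, 0.075]),
  and power corrected by the null 5% p-value quantile.
- **`mlmcorr.sim_driver`** — the Monte Carlo driver (conditions ×
  replications × the four method/model combinations RS-KR, RS-CRSEs,
  RI-CRSEs, OLS-CRSEs) with deterministic hierarchical seeding and tidy
  record/summary outputs.
- **`mlmcorr.diagnostics`** — Breusch-Pagan heteroscedasticity tests at
  both levels and plot-ready residual tables.

## CLI

```sh
# one simulated dataset to CSV
mlmcorr simulate -j 30 -n 30 --icc 0.3 --vp-l2 VP2 --unbalanced \
    --seed 1 --out data.csv

# fit a CSV (columns: cluster_id, y, predictors...) with a correction
mlmcorr fit --data data.csv --model rs --correction kr
mlmcorr fit --data data.csv --model ols --correction cr2

# heteroscedasticity diagnostics
mlmcorr diagnose --data data.csv --model rs --level1 x --level2 z

# Monte Carlo over a condition grid (YAML/JSON), then summarise
mlmcorr run-grid --config grid.yaml --reps 500 --seed 1 --out runs/
mlmcorr summarize --records runs/ --style table3
```

## Library API sketch

```python
from mlmcorr import (ConditionSpec, generate_dataset, ModelSpec,
                     fit_lmm, kr_inference, robust_inference)

cond = ConditionSpec(J=30, n_bar=30, icc=0.3, gamma01=0.3, gamma10=0.3,
                     balanced=False, vp_l1="VP1", vp_l2="VP2")
data = generate_dataset(cond, seed=1)
fit = fit_lmm(data, ModelSpec(kind="rs"))

from mlmcorr.kr_correction import kr_inference
print(kr_inference(fit).table())

from mlmcorr.robust_se import robust_inference, coef_table
print(coef_table(robust_inference(fit, "CR2")))
```
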