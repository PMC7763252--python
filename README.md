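# ecowarn

Ecological-security early-warning analysis for county-scale indicator
panels: entropy-weighted composite indexing, five-grade safety
classification, and per-region GM(1,1) grey forecasting with double
accuracy testing.

The package targets the situation common in regional ecological risk
assessment: a short panel (a handful of districts or counties, fewer than
ten years) of heterogeneous indicators spanning population, eco-environment,
socioeconomic and natural-resource subsystems (PESN), from which one wants a
single comparable safety score per region-year, a warning grade, and a
short-term forecast of how each region's score will evolve. It is written
for researchers and analysts doing this kind of multi-criteria indicator
work, where sample sizes are far too small for conventional time-series
models and grey-system methods are the standard tool.

## Method

**Composite index.** Raw indicators X_ij are min-max rescaled to [0, 1]
with direction-aware formulas — y = (x − min)/(max − min) for indicators
where more is safer, y = (max − x)/(max − min) where more is worse — with
min/max pooled over all (region, year) observations so scores are
comparable across years. Weights come from the entropy method:

    e_j = −(1/ln m) Σ_i f_ij ln f_ij,   f_ij = y_ij / Σ_i y_ij,
    w_j = (1 − e_j) / Σ_k (1 − e_k),

with zero frequencies replaced by 10⁻⁴. The early-warning value of a
region-year is P_i = Σ_j w_j y_ij, graded into five half-open bands:
[0, 0.2) I Huge alarm, [0.2, 0.4) II Moderate warning, [0.4, 0.6) III Light
warning, [0.6, 0.8) IV Good, [0.8, 1.0) V Excellent.

**Grey forecast.** Each region's P_i series feeds a GM(1,1) model: the
running sum x(1) (1-AGO) and adjacent-pair means z(1) enter the grey
difference equation x(0)(k) + a z(1)(k) = b, solved for (a, b) by least
squares; the time-response function x̂(1)(k+1) = (x(0)(1) − b/a)e^(−ak) + b/a
is differenced back to fitted values (or restored by the derivative form
−a(x(0)(1) − b/a)e^(−ak) for prediction). The fit is accepted only if the
double accuracy test passes: posterior error ratio C = S2/S1 and small-error
probability p graded on the standard four-level table, plus relative-error
and stage-ratio-deviation checks.

## Worked example

The shipped composite early-warning series (2011–2018) fit end to end:

```python
from ecowarn import diagnose, fit_gm11, forecast, load_fixture

series = load_fixture("comprehensive_s44")
fit = fit_gm11(series)
print(fit.a, fit.b)          # -0.1502069962074196 0.3310377102730445
rep = diagnose(fit)
print(rep.C, rep.verdict)    # 0.3786987757568876 Good
print(forecast(fit_gm11(series, restore="derivative"), 3)["predicted"].round(4).tolist())
# [1.1955, 1.3892, 1.6144]
```

The negative development coefficient a says the index is growing at about
15% per accumulated step; C ≈ 0.38 sits in the "Good" band of the posterior
error table, so the model is usable for prediction; the 2019–2021 forecasts
exceed 1 (the derivative-form trend is unbounded) and clamp to grade V when
classified. The same numbers are printed by `analysis/03_worked_example.py`;
`analysis/01`–`04` run the full chain — synthetic panel generation, entropy
weights and grading, the worked-example fit, per-county fits and forecasts —
writing tables under `results/`.

A command line wraps the same pipeline:

```sh
ecowarn synth --seed 4 --out panel.csv
ecowarn run --panel panel.csv --horizon 3 --out out/
```

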