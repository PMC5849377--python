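# fuzzyair

Mamdani fuzzy inference modelling of the short-term effect of air pollution
on pediatric respiratory hospitalizations, with the validation machinery
(lagged Pearson correlation and ROC/AUC with 95% confidence intervals) and a
calibrated synthetic-data generator.

## The problem

Daily hospital admissions of young children for respiratory disease (ICD-10
J00–J99) track ambient PM10 and NO2, with temperature and wind speed acting
protectively through pollutant dispersion. In sugarcane-growing regions of
interior São Paulo state the July–September straw-burning season drives a
pronounced pollution peak. Conventional analyses use Poisson time-series
regression; a fuzzy rule-based model is an interpretable, low-cost
alternative that a hospital manager can read as plain language ("if PM10 is
unacceptable and wind is weak, expect many admissions") while still
producing a daily numeric forecast.

## The model

Four inputs, each a linguistic variable with two complementary trapezoidal
terms forming a partition of unity (`μ_acceptable(x) + μ_unacceptable(x) = 1`):

| input | terms | default crossover segment |
|---|---|---|
| PM10 (µg/m³) | acceptable / unacceptable | 15–35 |
| NO2 (µg/m³) | acceptable / unacceptable | 40–80 |
| temperature (°C) | low / high | 22–32 |
| wind (m/s) | weak / strong | 1.8–2.8 |

The output (expected daily hospitalizations, domain [0, 9]) carries five
terms — L, ML, M, MH (triangles) and H (upper-shoulder trapezoid). A
16-rule base covers the full 2×2×2×2 factorial of input terms; severity
rises from L (all inputs favorable) to H (both pollutants unacceptable, low
temperature, weak wind). Inference is classical Mamdani: `min` conjunction
and implication, `max` aggregation, centroid defuzzification on a 1001-point
grid,

```
ŷ(x) = ∫ u · μ_agg(u) du / ∫ μ_agg(u) du,   μ_agg(u) = max_r min(α_r, μ_{C_r}(u))
```

where `α_r = min_i μ_{A_{r,i}}(x_i)` is rule r's firing degree. Under the
default calibration a PM10 reading of 24 µg/m³ is 0.55 acceptable / 0.45
unacceptable.

Validation compares exposure day t against counts on day t+lag for lags
0–3: Pearson r with the two-sided t-test p-value, and ROC AUC (equal to the
Mann–Whitney statistic, ties ½) of each pollutant and of the model's
prediction against counts dichotomized at >2 hospitalizations, with
Hanley–McNeil (default) or DeLong 95% intervals.

## Worked example

```python
import fuzzyair as fa

fis = fa.build_hospitalization_fis()
fis.inputs[0].fuzzify(24.0)
# {'acceptable': 0.55, 'unacceptable': 0.45}
fis.infer({"pm10": 140, "no2": 120, "temperature": 5, "wind": 0.5})
# 8.300009999999999   (centroid of the fully activated H term)
```

The analysis scripts run the whole pipeline on synthetic data:

```bash
python analysis/01_simulate.py   # 730-day series calibrated to the study region
python analysis/02_predict.py    # daily fuzzy predictions
python analysis/03_validate.py   # lagged Pearson + ROC table
```

`03_validate.py` prints, for the default seed:

```
Pearson correlation, model prediction (day t) vs observed counts (day t+lag):
  lag 0: r = 0.380 (p = 1.87e-26, n = 730)
  lag 1: r = 0.286 (p = 3.82e-15, n = 729)
  lag 2: r = 0.231 (p = 2.81e-10, n = 728)
  lag 3: r = 0.211 (p = 9.06e-09, n = 727)
```

i.e. the model is most informative for same-day admissions, with the
correlation decaying as the lag grows — the signature expected when the
underlying risk is driven mainly by same-day and recent exposure. The ROC
table (`results/roc_table.csv`) shows the same ordering: every predictor
discriminates high-admission days best at lag 0.

The same pipeline is available as a CLI
(`fuzzyair simulate|predict|validate|run`), e.g.

```bash
fuzzyair run --n-days 730 --seed 42 --outdir results/demo
```

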