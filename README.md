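# barnflux

Estimation and prediction of NH₃ and CH₄ concentrations and emission rates
in naturally ventilated dairy barns.

Open dairy housing cannot be fitted with flow meters: the air exchange with
the outside must be inferred. `barnflux` implements the indirect **CO₂
mass-balance method** — the herd's metabolic CO₂ production acts as a tracer
gas — and couples it to a **multilayer perceptron** that predicts gas
concentrations and emissions from barn microclimate, cow behaviour and diet,
including a systematic input-variable ablation study that ranks those input
groups. A seeded synthetic-campaign generator with known latent truth makes
every stage testable end to end without any measurement data.

The package is aimed at researchers in precision livestock farming and
agricultural emission inventories who want a reproducible, scripted version
of this workflow.

## The model

Per-cow total heat production, its temperature correction and the CO₂
excretion rate:

    qt    = 5.6 m^0.75 + 1.6·10⁻⁵ p³ + 22 y          (W)
    CF    = 4·10⁻⁵ (20 − Tᵢ)³ + 1
    qcor  = qt · CF                                   (W)
    P_CO2 = 0.299 · qcor                              (g cow⁻¹ h⁻¹)

with m the mean animal mass (kg), p days after insemination, y milk yield
(kg d⁻¹) and Tᵢ the indoor temperature (°C). The barn ventilation rate and
gas emissions then follow from indoor–outdoor concentration gradients
(g m⁻³):

    Q  = P_CO2 · N / (C_CO2,in − C_CO2,out)           (m³ h⁻¹)
    Et = Q · (C_in − C_out)                           (g h⁻¹)
    E  = Et · 500 / (N · m)                           (g LU⁻¹ h⁻¹, 1 LU = 500 kg)

Behaviour enters through two hourly indices derived from 15-min scan
sampling: the Cow Lying Index (fraction lying) and the Cow Activity Index
(fraction standing/walking/feeding).

Prediction uses a 20–10 perceptron (tansig hidden, linear output) trained by
Levenberg–Marquardt with early stopping on a 70:15:15 train/validation/test
split and min/max normalization fitted on training rows only. Models are
deemed satisfactory when R > 0.80 and R² > 0.70 on held-out data.

## Worked example

```python
import barnflux as bf
from barnflux.report import prepare_target
from barnflux.dataset import feature_sets

study = bf.gen_study(bf.GeneratorConfig())        # 718 hourly records, seed 42
res = bf.MassBalanceModel(study.records, study.config.herd, gas="NH3").estimate()
print(res.summary())
```

```
CO2 mass-balance emission estimates - gas NH3
hours: 718  ok: 718  invalid_gradient: 0  negative_emission: 0
Q  (m3 h-1):    mean      16516.4
Et (g h-1):     mean        8.823
E  (g LU-1 h-1): mean      0.1271
```

The barn exchanges ~16 500 m³ of air per hour and emits ~8.8 g NH₃ per hour,
i.e. 0.127 g per 500-kg livestock unit per hour. Training the full-input
concentration model on the same study:

```python
df = prepare_target(study, "NH3_concentration")
cfg = feature_sets("NH3_concentration")[-1]       # climate + activity + diet
fit = bf.MLPRegression.from_dataframe(
    df, cfg.target_column, cfg.feature_columns, split=study.split()
).fit(seed=0)
print(fit.summary())
```

```
MLP regression results
==============================================================
structure: 20-10   inputs: 24   parameters: 721
epochs: 9 (best 3)   stop: patience
partition       n       R      R2        MSE     RMSE      MAE       SD
--------------------------------------------------------------
train         502   0.862   0.744   0.005167  0.07188  0.05687  0.07182
validation    108   0.841   0.707   0.006673  0.08169  0.06627  0.08168
test          108   0.863   0.744    0.00586  0.07655  0.06264  0.07653
```

Test-partition R = 0.86 and R² = 0.74 clear the satisfaction thresholds:
the network recovers essentially all of the predictable signal (the
generator's signal-to-noise ratio of 3 caps attainable R² at 0.75).
`barnflux.run_ablation(study, target)` repeats this for every input-variable
configuration (7 for concentrations, 15 for emissions) and renders the
comparison table; `barnflux.report.export_timeseries/export_regression`
write prediction plots and their underlying data.

A `barnflux` command-line tool wraps the same pipeline
(`simulate`, `estimate-emissions`, `train`, `ablate`).

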