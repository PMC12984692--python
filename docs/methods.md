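# Methods

## CO₂ mass-balance estimation

The estimator treats the herd's metabolic CO₂ as a tracer: per-cow heat
production `qt = 5.6 m^0.75 + 1.6e-5 p³ + 22 y` (W) is corrected for indoor
temperature by `CF = 4e-5 (20 − Ti)³ + 1` and converted to a CO₂ excretion
rate `P_CO2 = 0.299 qcor` (g cow⁻¹ h⁻¹). Dividing the herd's total excretion
by the indoor–outdoor CO₂ gradient gives the ventilation rate Q; multiplying
Q by the NH₃ or CH₄ gradient gives the emission rate Et; normalizing by herd
mass in 500-kg livestock units gives E. Assumptions: steady state within the
hour, well-mixed indoor air (indoor sampling points are averaged — the
estimator averages *all* indoor points present rather than a fixed four),
and negligible non-animal CO₂ sources (manure CO₂, a few percent in barns
without deep litter, is not corrected for).

Numerical policies:

* **Invalid gradient.** When `C_CO2,in − C_CO2,out ≤ 1e-6 g m⁻³` the balance
  is undefined; the hour is flagged `invalid_gradient` (Q = NaN) instead of
  raising, so series processing continues. The guard is far below sensor
  resolution.
* **Negative emissions.** A negative gas gradient yields a negative Et. The
  default policy keeps and flags such hours (preserving series length for
  downstream modelling); `zero` and `drop` policies are available.
* **Units.** The balance consumes mass concentrations (g m⁻³). Instrument
  readings in ppm are converted by the ideal-gas relation at the hour's
  indoor temperature and 101.325 kPa (molar masses 17.031, 16.043,
  44.010 g mol⁻¹ for NH₃, CH₄, CO₂); the conversion is exactly invertible.

## Behavioural indices

Scan sampling counts cows lying, standing, walking and feeding every 15
minutes. CLI = lying/total, CAI = active/total; with the default active set
(standing, walking, feeding) the two indices are exact complements. Hourly
values are arithmetic means of the scans within each clock hour; an hour
without scans is missing, never zero. Which behaviours count as "active" is
configurable (the literature varies on whether feeding is included).

## Synthetic campaigns

The generator emulates one November month of hourly records from a
Mediterranean free-stall barn housing 56 Friesian cows: 720 hours minus two
maintenance hours = 718 records. Its purpose is structural: every
statistical relationship the pipeline is supposed to exploit is present by
construction, with the latent truth stored for verification.

* **Climate.** Outdoor temperature follows a time-warped daily cosine
  (minimum 05:00, maximum 14:00, default mean 14 °C, range 6 °C) plus AR(1)
  noise; indoors sits 2.5 °C warmer (animal heat). Humidity is inversely
  coupled to temperature and clipped to [0, 100] %; wind direction wraps to
  [0, 360)°; wind speeds are floored at small positive values.
* **Behaviour.** Scan counts are multinomial draws of the whole herd from
  smooth diurnal probabilities: lying peaks at night, feeding after the noon
  feed delivery, standing around the 06:00/18:00 milkings.
* **Diet.** The printed ration schedule (13 ingredients, changes on days 1,
  11, 18, 20, 22, 26, 30) ships as a packaged CSV; each hour carries its
  day's ration.
* **Concentrations.** The latent ventilation rate is
  `Q = 15000 (1 + 0.05 WS_out)` m³ h⁻¹ — a phenomenological wind-driven
  exchange, not an airflow model. True NH₃ emission is
  `4 (1 + 0.15 (T_in − 10)) (1 + 0.10 CAI) (1 + 0.005 h_clean)` g h⁻¹
  (temperature-dominated, increasing in activity and hours since the 07:00
  cleaning); true CH₄ emission is
  `800 (diet_total/50) (1 + 0.25 feedpeak) (1 + 0.10 CAI)` g h⁻¹ with a
  Gaussian post-feeding peak. Indoor concentrations follow the balance
  exactly: `C_in = C_out + E/Q` (and `P_CO2·N/Q` for CO₂), converted to ppm
  at the hour's indoor temperature, floored at the instrument detection
  limits (0.2 / 0.4 / 1.5 ppm for NH₃ / CH₄ / CO₂). Outdoor baselines are
  constant (420 ppm CO₂, 2 ppm CH₄, 0.25 ppm NH₃).
* **Noise.** Gaussian noise on the indoor channels with variance
  `var(signal)/snr`, default snr = 3. With snr = ∞ and climate noise 0 the
  mass-balance estimator inverts the generator to machine precision, which
  is the backbone of the estimator tests.

The coefficients above were chosen so the emission signal is a smooth,
temperature-dominated function that the fixed 20–10 network can represent
essentially exactly — the premise of the prediction study is that the
full-input model is satisfactory, and a generator whose truth the reference
architecture cannot express would test the wrong thing. What the generator
deliberately does **not** emulate: sensor drift, missing-data patterns
beyond the two maintenance hours, manure-management events, seasonal trends
or real inter-variable correlations of a commercial barn. Passing tests
therefore demonstrate correctness of the pipeline's mechanics, not
field-scale predictive skill.

Herd covariate defaults (mass 620 kg, 120 d after insemination, 28 kg d⁻¹
milk) are plausible mid-lactation Friesian values; feed delivery is
interpreted as noon. Everything is configurable through `GeneratorConfig`,
and identical config + seed reproduces files byte for byte.

## Dataset assembly

Features are organised in four groups — climatic (hour of day plus 8
indoor/outdoor weather variables), activity (CLI, CAI), diet (13 ingredient
masses) and, for emission targets only, concentrations (indoor/outdoor CO₂
and target gas). The ablation enumerations are fixed: 7 configurations for
concentration targets, 15 for emission targets. Hour of day and wind
direction enter as raw numbers (matching the flat variable list of the
study design); optional circular encodings exist behind flags.

Min/max normalization maps training-row ranges onto [−1, 1] (the natural
input range of tanh units); parameters are fitted on training rows only, and
constant features map to 0 with a logged warning. Both inputs and the target
are normalized; all metrics are computed on de-normalized values.

The 70:15:15 split uses a seeded uniform permutation with largest-remainder
size rounding (remainder ties broken in train → validation → test order);
718 rows give 502/108/108. **The split is part of the dataset definition**:
it is seeded by the study seed so that repeated trainings and all ablation
rows share one test partition and remain comparable. Repeat seeds vary the
network initialization. This matters statistically: at snr = 3 the
attainable test R² is capped at snr/(1+snr) = 0.75, and the sampling
spread of R² on a 108-row partition is ±0.03–0.04 across alternative
splits — re-randomizing the partition per repeat would dominate the
comparison with split luck rather than model quality (even the noiseless
signal itself fails R² ≥ 0.70 on some partitions).

## Network and training

The perceptron uses tansig hidden and linear output units. Weights are
initialized from U(−s, s) with s = 1/√fan-in, seeded. Training is
Levenberg–Marquardt: per epoch the residual Jacobian is assembled by
back-propagation, the Gauss–Newton system `(JᵀJ + μI)δ = Jᵀr` is solved by
Cholesky factorization (J ᵀJ formed once per epoch, re-factorized per
damping retry — algebraically identical to the textbook update, much
faster), and μ is divided by 10 on an accepted step or multiplied by 10 and
retried otherwise (μ₀ = 0.001, cap 10¹⁰). Defaults: 1000 epochs maximum,
error goal 0, no weight decay. Early stopping halts after 6 consecutive
validation checks without improvement over the best value and restores the
best-validation weights (early stopping without restoration would be
incoherent). Stop reasons: `patience`, `max_epochs`, `mu_overflow`, `goal`.

The incremental structure search evaluates [5] → [10] → [20] → [20, 10] →
[40, 20] — widen the single hidden layer, then append a half-width second
layer — stopping at the first structure whose validation R and R² clear the
satisfaction thresholds (R > 0.80, R² > 0.70); ties favour fewer
parameters, and if nothing satisfies, the best-so-far structure is returned
with its full search log. The intermediate widening steps are an
interpretation (the reference procedure is summarized only as a flowchart);
the log records every evaluated step.

## Metrics and ablation reporting

Six metrics per partition: R (Pearson), R² (squared correlation of targets
vs predictions — matching the regression-analysis convention of the
environment the settings mirror; the 1 − SSE/SST variant is also computed
as `R2_ss`), MSE, RMSE, MAE and SD (population standard deviation of
residuals; SD = RMSE exactly when the mean residual vanishes, which is why
the two columns track each other for unbiased models). Constant predictions
make R undefined: reported as NaN with a warning, error metrics intact.

The ablation runner trains the fixed 20–10 structure on each configuration,
evaluates the test partition by default (both test and all-data reports can
be produced) and renders the table layout Variables / ANN Structure / R /
R² / MSE / RMSE / MAE / SD. Emission targets are first derived from the
records by the mass-balance estimator, so their ablation inherits its flags;
invalid-gradient hours are dropped with a logged count.

## Problem sizes

Default experiments run on the 718-record campaign: a single 20–10 training
takes well under a second on one CPU core (the Jacobian is 502 × 721), a
ten-repeat satisfaction check a few seconds, and the full 7 + 15-row
ablation pair a few minutes, dominated by the near-noiseless
concentration-input emission rows that train to many epochs.

## Known limitations

* The generator's distributional defaults are stand-ins: no published
  means/variances of the emulated campaign exist to calibrate against, so
  absolute emission magnitudes are plausible rather than validated.
* The measured-data metric values of the original input-ranking tables are
  not reproducible without the (unreleased) campaign data; only their
  qualitative structure — row layout and input-group ordering — is
  reproduced on synthetic data.
* R² as squared correlation is insensitive to calibration offsets; the
  `R2_ss` variant is reported alongside for that reason.
* The Jacobian path assumes a single output unit (all study targets are
  scalar).
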