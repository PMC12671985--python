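# Methods

## The calibration problem

Optical particle counters estimate PM2.5 mass from light scattering.
Scattering depends on particle size and refractive index, both of which
change as hygroscopic particles take up water, so raw readings
overestimate mass at high relative humidity — severely so in humid
equatorial climates. The remedy is collocation: operate the sensor next
to a trustworthy reference, learn a mapping from (raw signal,
meteorology) to reference mass, and apply that mapping network-wide.

The reference here is itself a two-part instrument: a nephelometer
(5-min light-scattering readings, also composition-biased) paired with
weekly 47-mm gravimetric filters. The filter mass is the ground truth;
each week's nephelometric stream is rescaled by the ratio of the
filter-derived mean concentration to the nephelometric weekly mean (the
*gravimetric correction factor*, CF), then averaged to hours.

## Model

The calibration regression family is

    PM2.5_ref(t) = β0 + β1·PA_cf1(t) + γ'·met(t) + ε(t)

where `PA_cf1` is the hourly mean of the sensor's two channels (cf=1
convention) and `met` ranges over subsets of {RH, T, DP, P} with at
most one pairwise interaction (eleven linear specifications), plus
random-forest, XGBoost, penalized-spline GAM
(`β0 + s(PA_cf1) + s(RH)`), and ARIMAX(24,1,6) alternatives, and a
fixed U.S.-wide benchmark (5.75 + 0.524·PA − 0.0862·RH) used for
comparison only. The shipped default final model is the RH-only linear
form: in this climate RH carries nearly all the correctable bias, and a
two-covariate linear correction is transparent enough to deploy on
resource-limited monitoring programmes.

Assumptions worth stating: the calibration is *static* (no sensor drift
over the deployment), *site-transferable* (learned at one rural
collocation site, applied network-wide), and *linear in the raw
signal* over the observed concentration range. Residual noise ε is
treated as reference-side and independent of the raw signal.

### Temporal structure and evaluation

Ambient PM is strongly autocorrelated, so random train/test splits leak
information. The pipeline uses a chronological 80/20 split rounded down
to whole 24-hour days (a fraction 0.8 of N hours, floored to a multiple
of 24: 7236 hours → 5784 train / 1452 test), and expanding-window
cross-validation inside the training set (initial window 576 h, fixed
576-h validation horizon, 576-h step) for hyperparameter tuning.
Metrics: RMSE, bias and MAE (µg/m³, predicted − reference), MAPE (%),
Pearson-R², Spearman ρ, and Bland–Altman mean difference with
±1.96 SD limits of agreement. MAPE is safe because reference values are
floored at 1/√2 µg/m³ upstream.

### QC rules and tunables

| parameter | default | meaning |
|---|---|---|
| `pct_threshold` | 70 % | A/B deviation as % of channel mean |
| `abs_threshold` | 5 µg/m³ | absolute A/B deviation |
| `min_completeness` | 0.75 | fraction of the 30 expected 2-min intervals per hour |
| `floor` / `substitute` | 1 / 1/√2 µg/m³ | low-concentration substitution |
| `residual_k_sd` | 2 | one-pass residual outlier cut on the full linear model |
| `train_fraction` | 0.8 | chronological split |
| `cv_initial/horizon/step` | 576 h | expanding-window CV geometry |
| `wet_months` | {3,4,5,9,10,11} | bimodal rainfall calendar |
| `idw_power` | 2 | inverse-distance weighting exponent |

An hour is excluded only when the channel deviation exceeds **both**
thresholds (AND semantics); the percent denominator is the channel mean
(A+B)/2, with the (0,0) case defined as 0. The two-threshold AND is
deliberate: at very low concentrations large percentage deviations are
meaningless, and at high concentrations a 5 µg/m³ absolute deviation is
routine. The low floor is applied after channel averaging; the two
orders differ only below 1 µg/m³. Hour bins are left-closed and
labelled by their start; all timestamps are naive local clock time
(UTC+3 region, no DST), which is what diurnal summaries should use.
There is no published completeness rule for this sensor family;
0.75 is configurable and `0` disables the filter.

### Gravimetric chain

LOD = 3 × sample SD (ddof 1) of blank net masses; blank-corrected
masses below the LOD are censored to LOD/√2. Concentration =
mass / (flow × minutes / 1000) with mass in mg converted to µg. CF
fences use linear-interpolation quantiles (the common default;
configurable since the rule is not standardized) with *strict*
inequalities at the fence values; the replacement value is the median
of the raw, pre-replacement CFs. 5-min nephelometric values under
1 µg/m³ are substituted with 1/√2 *before* CF multiplication.

### Dew point

Magnus–Tetens with a = 17.27, b = 237.7 °C (configurable):
γ = aT/(b+T) + ln(RH/100), DP = bγ/(a−γ). DP = T at saturation and is
monotone in RH.

### Rank-based trend tests

Mann–Whitney U uses exact enumeration for pooled n ≤ 12 without ties,
otherwise the normal approximation with midrank-tie and continuity
corrections. The setting × season interaction uses the
Scheirer–Ray–Hare extension of Kruskal–Wallis: two-way ANOVA sums of
squares computed on global midranks, each scaled by the total rank
variance SS_total/(N−1), referred to χ² with the effect df. An
all-tied input returns H = 0, p = 1 for every effect. The "nonparametric
factorial" could equally be realized as an aligned-rank transform; SRH
was chosen for its closed form and testable χ² null.

## Synthetic-data generator

The generator is first-class, tested code; its defaults emulate the
deployment the pipeline was designed for.

* **True PM**: baseline + 6-month-period seasonal cosine (maxima in the
  two dry seasons) + double-peaked diurnal template (Gaussian bumps at
  07:30 and 20:00, evening higher) + AR(1) noise (ρ = 0.6, SD 3 µg/m³),
  clipped at 0. Setting presets: rural baseline 17.4 µg/m³ (seasonal
  half-amplitude 4.7), urban 30.4 (7.2), with city presets 26.5 and
  37.0 for the smaller and larger city — chosen so pooled seasonal
  means land near the field values (rural ≈22 dry / ≈13 wet, urban
  ≈38 / ≈23 µg/m³).
* **RH**: configured monthly-mean cycle spanning 73.8 % (January) to
  86.3 % (November), an anti-phase diurnal component (driest
  mid-afternoon), AR(1) noise, clipped to [20, 100].
* **Raw sensor**: the calibration relation inverted,
  `raw = (true − β0 − β2·RH)/β1` floored at 0, so the regression of
  reference on (raw, RH) has exactly the generator's coefficients as
  estimand. Channels A/B multiply the latent raw by independent
  mean-one lognormal noise (σ = 0.02, the few-percent inter-channel
  agreement of healthy dual-channel sensors). 2-min disaggregation
  interpolates between hour centres and then rescales each hour's 30
  intervals so their mean equals the hourly value exactly — plain
  interpolation smooths across hours and would attenuate the recovered
  slope (errors-in-variables), breaking the estimand identity the
  generator exists to provide. Fault hours (rate configurable) scale
  one channel by U[2, 5] to trip the A/B filter; a configurable
  fraction of hours is dropped entirely.
* **Reference**: the residual scatter of the calibration relation
  (SD 4.44 µg/m³) is injected as hourly additive Gaussian noise on the
  reference side, independent of the raw signal. Weekly true CFs are
  lognormal around 1.30, truncated at ±2 SD (σ_log = 0.12); the
  nephelometer stream is (true + noise)/CF with small multiplicative
  instrument noise. Filter masses integrate true concentration over
  the 20.16 m³ weekly volume, plus a blank artifact (mean 0.020 mg) and
  weighing noise (SD 0.003 mg); three field blanks carry the artifact
  only (SD 0.008 mg). A `cf_outlier_rate` knob corrupts the *filter
  mass* of random weeks by ×[0.3, 0.5] or ×[1.8, 2.5] — the gross
  handling artifacts the Tukey-fence rule exists to repair, and the
  property suite verifies that it does.

**What the generator does not emulate**: aerosol optics and
hygroscopic growth physics (the RH bias enters only through the linear
relation), particle-composition changes, sensor drift and aging,
spatially correlated weather across sites, wind transport, and
real-world missingness patterns (gaps are MCAR). Passing recovery
tests therefore demonstrate that the *pipeline estimates what it claims
to estimate under its own model*, not that the linear RH model is an
adequate physical description of any particular sensor.

### Identifiability choices, and a known bias

Two generator-level choices were made specifically so the recovery
estimand stays identified: the residual noise lives on the reference
side (noise inside the raw-signal inversion would correlate with the
regressor and bias OLS), and gravimetric weighing/blank noise is kept
at careful-laboratory scale so weekly CFs are recoverable — with large
blank variability the shared blank-correction error becomes a common
multiplicative bias on the whole reference series that no estimator
can remove.

Even so, end-to-end recovery is not exact: channel-noise
errors-in-variables attenuates the slope by ≈0.4 %, and weekly CF
estimation noise contributes ≈1 % common-scale error at a 12-week desk
scale. The end-to-end tests therefore assert tight relative error on
replicate means and majority CI coverage rather than nominal 95 %
coverage; the direct (generation → OLS) recovery experiment, which has
none of these chain effects, recovers coefficients and residual SD to
within Monte-Carlo error.

## Numerical choices

* The one-pass residual outlier cut treats a residual SD at float
  round-off scale (≤1e-10 × response SD) as an exact fit and removes
  nothing.
* Gaussian residuals trimmed at ±2 SD have SD ≈0.88σ, so residual SDs
  refitted after the outlier pass sit below the generating σ by that
  factor; the recovery experiment reports the untrimmed fit.
* GAM smooths are cubic B-splines (df 10 per smooth, penalty α = 1);
  predictions clamp inputs to the training range because splines do
  not extrapolate.
* ARIMAX differencing applies to the reference series only; exogenous
  regressors enter undifferenced. Convergence failures are flagged and
  the model is dropped from the comparison with a warning, not raised.
* RF/XGBoost default to their tuned optima (ntree 100 / mtry 4;
  nrounds 100 / η 0.1 / depth 4); setting `tune=True` re-tunes over a
  20-point grid scored by expanding-window CV RMSE.
* IDW uses haversine great-circle distances, power 2, an exact-hit
  tolerance of 1 m, and is a convex combination (bounded by the input
  value range).
* Duplicate sensor-log timestamps keep the last occurrence (SD-card +
  cloud merges duplicate rows); malformed rows are counted and logged.

## Problem sizes

The test suite runs everything at desk scale: end-to-end recovery uses
12 replicates of 90 days; the direct recovery experiment uses 100
replicates of 5784 hours (cheap, pure OLS); the pipeline integration
test simulates 4 sites × 35 days; rank-test calibration uses 150–300
null simulations of n = 80. These sizes were chosen so the whole suite
completes in well under a minute while every statistical check retains
enough power to fail loudly when a rule is wrong.

## Limitations

* The final model is chosen by configuration (default: the linear RH
  model), not auto-selected; the comparison table is reported for the
  user to judge.
* The gravimetric chain assumes one filter per week and does not
  standardize sampled volume for temperature/pressure.
* Season labels are fixed month sets; rainfall timing in the region is
  becoming less regular, and the month sets are configurable for that
  reason.
* Stratum summaries are observation-weighted (sites with more uptime
  contribute more hours), not site-weighted.
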