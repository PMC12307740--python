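# osaclim

Seasonal and environmental modulation of nightly obstructive sleep apnea
(OSA) severity, estimated from long-running multi-night home monitoring.

## The problem

OSA severity is usually summarised by the apnea–hypopnea index (AHI,
respiratory events per hour of sleep) measured on a single clinic night —
yet the AHI fluctuates strongly from night to night (within-person
coefficient of variation around 50%). With consumer sleep monitors recording
hundreds of nights per person, one can ask whether part of that fluctuation
is systematic: does OSA severity track the time of year, ambient
temperature, air pressure, or how long a person slept?

`osaclim` implements that analysis as a tested, reusable pipeline for
epidemiologists and sleep researchers working with nightly AHI panels:

1. **Outcome normalisation.** Each night is expressed as a relative change
   from the participant's yearly mean,
   `cAHI = 100 · (AHI − ĀHI) / ĀHI` (%), making nights comparable across
   severities.
2. **Cohort QC.** Regular-use inclusion rules (≥4 recordings per active
   week, ≥28 valid nights per year, yearly mean AHI ≥ 5 events/h; nights
   under 5 h of sleep are invalid) and per participant-year summaries
   (mean/SD/CV of AHI, habitual sleep duration, duration/timing
   irregularity, severity class: mild 5–15, moderate 15–30, severe >30).
3. **Exposure preparation.** Hourly environmental series are averaged to
   24 h means per location-day, relative humidity is derived from air and
   dew-point temperature (Magnus form), and every night is joined to the
   exposures of its onset date.
4. **Fixed-effects spline regression.** `cAHI` (or absolute AHI, or a
   binary severity indicator) is regressed on a natural cubic spline of
   day-of-year (domain day 1–365, default 8 df), day-of-week indicators,
   and optional confounder splines (4 df each), with a separate intercept
   for every participant×year cell. The Gaussian model absorbs the strata
   by within-cell demeaning (exactly equivalent to explicit dummy
   intercepts, including the residual-df correction); binary outcomes use
   conditional logistic regression, which eliminates the strata intercepts
   by conditioning.
5. **Marginal-effect summaries.** Estimated-marginal-mean curves relative
   to a reference setting (June 21 for the seasonal term), peak-to-trough
   seasonal deltas with parametric-simulation CIs, percentile contrasts
   (75th vs 25th; 95th/5th vs 50th for U-shapes), percent changes in odds,
   and minimal- vs fully-adjusted curve comparisons as a collinearity
   check.
6. **Synthetic cohorts with known truth.** A first-class simulator
   generates nightly panels (log-normal subject means targeting a cohort
   mean of 18 and SD of 14 events/h, gamma multiplicative nightly noise at
   50% CV, hemisphere-aware temperature cycles) with injected seasonal,
   temperature, sleep-duration and day-of-week effects, so every stage is
   testable by parameter recovery.

The statistical core is exposed as sklearn-style estimators
(`NaturalSplineFeatures`, `StrataAbsorbedOLS`,
`ConditionalLogisticRegression`, `FixedEffectsSplineModel`) with
`fit`/`transform`, `get_params`/`set_params` and trailing-underscore fitted
attributes.

## Worked example

```python
import osaclim as oc

cfg = oc.SimConfig(n_participants=200, years=(2021,), seasonal_amplitude=10.0,
                   temp_effect=0.5, seed=42)
exposures = oc.simulate_band_exposures(cfg)
records, truth = oc.simulate_cohort(cfg, exposures)

retained = oc.filter_regular_users(oc.flag_valid_nights(records))
summaries = oc.summarize_participant_year(retained)
valid = retained[retained["valid"]].merge(
    summaries[["participant_id", "year"]], on=["participant_id", "year"])
nights = oc.derive_nights(valid, summaries, oc.daily_average(exposures))

model = oc.FixedEffectsSplineModel(seasonal_df=8, confounders=[("temp_c", 4)])
model.fit(nights)
curve = oc.peak_trough(model.result_, reference=172.0, seed=0)
contrast = oc.percentile_contrast(model.result_, "temp_c", nights, 75, 25)

print(f"{model.n_obs_} analysis nights, {model.n_strata_} participant-years")
print(f"median within-subject CV: {summaries['cv'].median():.1f}%")
print(f"seasonal peak-trough delta: {curve.delta:.1f}% "
      f"(95% CI {curve.delta_ci[0]:.1f}-{curve.delta_ci[1]:.1f}), "
      f"peak day {curve.peak_day}, trough day {curve.trough_day}  "
      f"[injected: {truth.seasonal_peak_trough:.1f}%]")
print(f"temperature P75 ({contrast.setting_hi:.1f} degC) vs "
      f"P25 ({contrast.setting_lo:.1f} degC): +{contrast.estimate:.1f}% AHI "
      f"(95% CI {contrast.ci_low:.1f} to {contrast.ci_high:.1f})  "
      f"[injected: +{0.5*(contrast.setting_hi-contrast.setting_lo):.1f}%]")
```

Output (printed by the session above):

```
52684 analysis nights, 200 participant-years
median within-subject CV: 51.2%
seasonal peak-trough delta: 21.2% (95% CI 17.7-24.8), peak day 210, trough day 1  [injected: 20.0%]
temperature P75 (16.2 degC) vs P25 (5.8 degC): +5.4% AHI (95% CI 3.3 to 7.5)  [injected: +5.2%]
```

Reading: the cohort's night-to-night AHI variability matches the configured
50% CV; the temperature-adjusted seasonal fit recovers the injected 20%
peak-to-trough swing; and the temperature contrast recovers the injected
0.5 %/°C slope times the interquartile range of daily temperature.

The same analysis runs from a shell against a YAML config:

```sh
osaclim all --config run.yaml --outdir results --seed 1
```

writing seasonal curves (365-day grid), contrast tables, adjustment
comparisons, the cohort summary, and a manifest (config hash, seed, file
digests); identical config and seed reproduce byte-identical bundles.

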