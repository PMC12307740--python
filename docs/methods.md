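# Methods

`osaclim` analyses night-to-night variation in obstructive sleep apnea (OSA)
severity — the apnea-hypopnea index (AHI), events per hour of sleep — as a
function of season and environmental exposures, using multi-night home
monitoring data in long format (one row per participant-night). This note
describes the statistical model, the synthetic cohort the package tests
itself on, and the numerical and design choices a maintainer should know.

## Outcome and normalisation

Nightly AHI is heavily right-skewed between people (population mean ~18,
SD ~14 events/h) and noisy within a person (night-to-night coefficient of
variation around 50%). The primary outcome is therefore the *relative AHI
change*: for participant *p*, year *y*, night *d*,

    cAHI_{d,y,p} = 100 * (AHI_{d,y,p} − m_{y,p}) / m_{y,p}   [%]

where `m_{y,p}` is that participant's mean AHI over the valid nights of that
year. A +10% night means the same thing for a mild and a severe sleeper, so
seasonal effects can be pooled across severities. By construction cAHI is
bounded below by −100 and averages to zero within every participant-year.
Secondary outcomes: absolute AHI (events/h) and the binary indicators
AHI ≥ 15 (moderate-to-severe) and AHI ≥ 30 (severe).

## Cohort rules

- A night is *valid* when total sleep time (TST) ≥ 5 h (300 min, inclusive);
  AHI cannot be estimated reliably on shorter nights. Short nights still
  count as device use for adherence but never enter AHI statistics.
- A participant-year is retained when the device was used on average ≥ 4
  nights per active week (first to last recording of the year) and produced
  ≥ 28 valid nights, and the yearly mean AHI is ≥ 5 events/h (at least mild
  OSA). Mean-per-active-week, rather than every-calendar-week, enforcement
  is the default so ordinary recording gaps (holidays) do not evict
  otherwise dense users; both interpretations are supportable from the
  inclusion wording.
- Severity classes on the yearly mean: mild [5, 15), moderate [15, 30],
  severe > 30. The boundary values 15 and 30 are classified as moderate,
  matching a "severe is strictly above 30" reading.
- Sleep-duration and timing irregularity are the within-participant-year
  standard deviations of TST and of sleep onset (minutes); the names are
  standard but the estimator is not uniquely fixed in the literature, and SD
  matches how the dispersion of sleep duration is reported elsewhere in this
  kind of cohort.

## Exposures

Hourly series per location (2 m air temperature, dew point, total cloud
cover, wind speed, surface pressure, PM2.5) are averaged per calendar day;
days with fewer than 18 of 24 hours are treated as missing. Relative
humidity is derived from the daily temperature/dew-point means with the
Magnus form RH = 100·e(Td)/e(T), e(T) = exp(17.625·T/(243.04+T))
(Alduchov–Eskridge constants), clipped at 100%. Each night is joined to the
24 h means of its *onset* calendar date (the wake date is a defensible
alternative; onset is the default because the night is keyed to the evening
it starts). Day-of-year uses a 1–365 domain with February 29 mapped to 59.

## Model

Fixed-effects ("within") regression with one stratum per participant × year:

    cAHI ~ ns(day_of_year, df=8; boundary 1, 365) + day-of-week
           [+ ns(confounder, df=4) ...]       , strata (participant, year)

- **Strata absorption.** For the Gaussian family the per-stratum intercepts
  are removed exactly by within-stratum demeaning of the outcome and every
  design column (Frisch–Waugh–Lovell). Residual degrees of freedom subtract
  the number of absorbed strata, so the model-based covariance equals the
  explicit dummy-intercept OLS covariance (verified against statsmodels OLS
  in the tests). Cluster-robust (CR1, by participant) covariance is
  available; model-based is the default. Single-observation strata
  contribute nothing; columns constant within every stratum (e.g. yearly
  irregularity summaries) are exactly collinear with the strata intercepts,
  and are detected after demeaning and dropped with bookkeeping — adding
  them to a strata model is a no-op by construction, not an error.
- **Natural splines.** The seasonal and confounder terms use natural cubic
  splines: df basis columns, interior knots at equally spaced quantiles of
  the observed values, boundary knots at the data range (pinned to days 1
  and 365 for the seasonal term), linear beyond the boundaries. The basis is
  the truncated-power natural construction, affinely rescaled for
  conditioning; it spans the same function space as R's `splines::ns` with
  the same knots (checked against Rscript in the tests). The seasonal spline
  is deliberately *not* periodic; the Dec 31/Jan 1 discontinuity is accepted
  because the spline domain mirrors the calendar year.
- **Binary outcomes.** Strata intercepts are eliminated by conditional
  (strata-matched) logistic likelihood rather than thousands of dummies
  (incidental-parameter bias in short strata). The conditional likelihood's
  denominator recursion is combinatorial in stratum length, so strata longer
  than a configurable night budget (default 60) are randomly thinned, seeded
  from the run configuration, before fitting; conditioning remains valid on
  any subset of a stratum. Exactness at small scale is tested against the
  matched-pair closed form log(n10/n01). The optimizer is Newton (the
  default quasi-Newton stops short of the closed form by ~1e-5).

## Reported quantities

All effects are estimated-marginal-mean (EMM) contrasts — strata absorb all
level information, so only differences between two settings of a term are
identified:

- **Seasonal curve**: EMM over days 1–365 relative to a reference day
  (default June 21), delta-method pointwise 95% CIs.
- **Peak-to-trough delta (ΔAHI)**: curve maximum minus minimum over the
  integer-day grid (ties → earliest day). CI by parametric simulation:
  ≥10,000 coefficient draws from N(β̂, Σ̂), evaluating per draw the linear
  contrast between the point-estimate peak and trough days and taking
  2.5/97.5 percentiles. Recomputing the argmax inside every draw was tried
  first and undercovered in replicate experiments — max-minus-min of a noisy
  curve is upward biased, and the bias enters twice (point estimate and
  draws); fixing the days keeps the per-draw functional linear and restores
  near-nominal coverage. The point estimate itself retains the (small)
  argmax bias, visible as a fraction of a percentage point at desk scale.
- **Percentile contrasts**: EMM difference between the 75th and 25th
  percentile values of the exposure's pooled night-level distribution within
  the fitted group (95th/50th and 5th/50th for U/J shapes), delta-method CI.
  For binary fits the same contrast on log-odds, plus the odds ratio and the
  percent change in odds 100·(exp(contrast) − 1).
- **Adjustment comparison**: the minimally adjusted (term + season +
  day-of-week) and fully adjusted EMM curves for each exposure are compared
  over the 1st–99th percentile grid; a maximum divergence above 25% (config)
  of the curve range flags suspected collinearity.

## Synthetic cohort

The generator emulates the analysis-ready tables, not the measurement chain
(no sensor model, no sleep staging, no device error):

- Subject mean AHI: log-normal with log-mean 2.6539 and log-SD 0.6878
  (matching mean 18, SD 14 events/h), truncated at ≥ 5 to mirror inclusion.
- Nightly AHI = subject mean × (1 + injected effects in %/100, floored at 0)
  × gamma noise with unit mean and CV `night_cv` (default 0.50). Gamma
  multiplicative noise is a modelling convenience (positive support, CV
  directly parameterisable); the real within-subject distribution family is
  unknown.
- Injected effects combine additively inside the multiplicative factor:
  a mean-zero seasonal sinusoid (default amplitude 5% — half peak-to-trough
  — peaking mid-July, day 199), a temperature slope (% per °C about a
  reference temperature), a TST-deviation slope (% per minute, applied about
  the subject's generating habitual TST; the analysis recentres on the
  observed yearly mean, a Monte-Carlo-level mismatch), and day-of-week
  offsets (zero by default).
- Sleep: habitual TST ~ N(438, 45) min between subjects with nightly noise
  SD 60 min and a winter lengthening component (default 15 min amplitude);
  onset ~ N(270, 40) min after 18:00 between subjects, nightly SD 30 min.
- Adherence: nights recorded independently with probability
  `adherence/7 × (1 − missing_night_prob)` (defaults 5.5/week, 5% missing),
  giving realistic holes without weekly structure.
- Exposures: hourly temperature = location mean + seasonal cosine (amplitude
  8 °C, peak day 199, phase shifted half a year south of the equator) +
  diurnal cycle + day-level noise (SD 3 °C); dew point is temperature minus
  a gamma-distributed non-negative depression, so it never exceeds the air
  temperature; cloud/wind/pressure/PM2.5 are seasonal-plus-noise series with
  plausible ranges. Locations within a latitude band differ in mean
  temperature.

What passing recovery tests show — and what they do not: the pipeline
recovers injected effects under independent multiplicative noise, correct
exposure matching and ignorable missingness. Real data add device error,
behavioural confounding correlated with season, non-ignorable missingness,
and geocoding error, none of which the generator emulates.

## Problem sizes and numerics

- Recovery experiments run at 500 participants × 2 years (≈260k analysed
  nights) for the seasonal delta, 300–500 × 1 year for temperature, and
  200 × 1 year for null calibration — sizes at which Monte-Carlo error is
  a few tenths of a percentage point and a full experiment runs in seconds
  to a few minutes on one CPU.
- Least squares is solved from the normal equations after a pivoted-QR rank
  check; rank-deficient columns are dropped with a warning (never a crash)
  and reported on the fit. Dropped columns keep zero coefficient and zero
  covariance rows so marginal-mean code is uniform.
- Byte-stable outputs: CSVs are written with a fixed float format and the
  manifest hashes every file; identical configuration and seed reproduce
  identical bundles, which is asserted end to end in the tests.

## Known limitations

- The seasonal spline's non-periodicity biases the curve slightly near
  January 1 / December 31 when the true signal is smooth across the year
  boundary; with 8 df the effect on the peak-to-trough delta is well under
  the Monte-Carlo noise at desk scale. A periodic fit is not provided.
- Conditional-logistic thinning discards information in long strata; the
  estimate stays consistent but CIs are wider than an exact (infeasible)
  full-likelihood fit would give.
- The per-exposure confounder mapping is an editable default (each exposure
  adjusted for the remaining nightly-varying environmental terms); studies
  with a bespoke mapping should transcribe it into the configuration.
- No distributed-lag structures: only same-day exposures are modelled.
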