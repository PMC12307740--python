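"""Synthetic longitudinal cohort and environmental series with known truth.

The generator emulates the analysis-ready tables of a multi-night home sleep
monitoring study: nightly AHI per participant with a right-skewed
between-subject severity distribution (log-normal matched to a cohort mean of
18 and SD of 14 events/h, truncated at the mild-OSA inclusion floor of 5),
multiplicative within-subject night-to-night noise with a configurable
coefficient of variation (default 50%), and injected seasonal, temperature,
sleep-duration and day-of-week effects that act multiplicatively on the
subject mean — so the injected percentages are exactly what the relative
AHI-change outcome should recover.  Environmental series are hourly, with a
hemisphere-aware sinusoidal annual temperature cycle, a diurnal cycle, and
day-level weather noise; the dew point is the temperature minus a
non-negative depression so it can never exceed the air temperature.

Every injected function is recorded in :class:`SimTruth`, making each
downstream stage testable by parameter recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transforms import daily_average, day_of_year

LATITUDE_BANDS = {"30..90": 50.0, "0..30": 15.0, "-30..0": -15.0, "-90..-30": -50.0}


@dataclass
class ExposureParams:
    """Annual-cycle settings for one simulated location."""

    temp_mean_c: float = 11.0
    temp_seasonal_amp_c: float = 8.0     # half peak-to-trough of the annual cycle
    temp_diurnal_amp_c: float = 4.0
    temp_noise_sd_c: float = 3.0         # day-level weather noise
    summer_peak_doy: float = 199.0       # mid-July (northern hemisphere)
    dewpoint_depression_shape: float = 4.0
    dewpoint_depression_scale: float = 1.0
    pressure_mean_hpa: float = 1013.0
    pressure_noise_sd_hpa: float = 8.0


def _dates_for_years(years) -> pd.DatetimeIndex:
    years = sorted(set(int(y) for y in years))
    parts = [pd.date_range(f"{y}-01-01", f"{y}-12-31", freq="D") for y in years]
    return parts[0].append(parts[1:]) if len(parts) > 1 else parts[0]


def seasonal_temperature(doy, latitude: float, params: ExposureParams) -> np.ndarray:
    """Noiseless annual temperature cycle; phase shifts by half a year south of the equator."""
    peak = params.summer_peak_doy
    if latitude < 0:
        peak = (peak + 365.0 / 2) % 365.0
    doy = np.asarray(doy, dtype=float)
    return params.temp_mean_c + params.temp_seasonal_amp_c * np.cos(
        2 * np.pi * (doy - peak) / 365.0
    )


def simulate_exposures(
    location_id: str,
    latitude: float,
    years,
    params: ExposureParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Hourly environmental series for one location.

    Columns: location_id, timestamp, temp_c, dewpoint_c, cloud_cover,
    wind_speed, pressure_hpa, pm25.  Identical arguments give byte-identical
    output.
    """
    if not list(years):
        raise ValueError("no simulation period: empty year list")
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude must be in [-90, 90]")
    params = params or ExposureParams()
    rng = np.random.default_rng(seed)
    dates = _dates_for_years(years)
    n_days = len(dates)
    doy = day_of_year(dates)

    t_day = seasonal_temperature(doy, latitude, params)
    t_day = t_day + rng.normal(0.0, params.temp_noise_sd_c, n_days)
    depression = rng.gamma(params.dewpoint_depression_shape,
                           params.dewpoint_depression_scale, n_days)
    winter_doy = (doy - params.summer_peak_doy + 365.0 / 2) % 365.0
    cloud = np.clip(
        0.5 + 0.2 * np.cos(2 * np.pi * winter_doy / 365.0)
        + rng.normal(0.0, 0.22, n_days),
        0.0, 1.0,
    )
    wind = rng.gamma(2.0, 2.0, n_days)
    pressure = params.pressure_mean_hpa + rng.normal(
        0.0, params.pressure_noise_sd_hpa, n_days
    )
    pm25 = np.exp(rng.normal(2.4, 0.5, n_days))

    hours = np.arange(24)
    diurnal = -0.5 * params.temp_diurnal_amp_c * np.cos(2 * np.pi * (hours - 15) / 24.0)
    hourly_jitter = rng.normal(0.0, 0.3, (n_days, 24))
    temp_h = t_day[:, None] + diurnal[None, :] + hourly_jitter
    dew_h = temp_h - depression[:, None] - np.abs(hourly_jitter)  # stay below temp

    ts = dates.values[:, None].astype("datetime64[h]") + hours.astype("timedelta64[h]")
    out = pd.DataFrame(
        {
            "location_id": location_id,
            "timestamp": ts.reshape(-1),
            "temp_c": temp_h.reshape(-1),
            "dewpoint_c": dew_h.reshape(-1),
            "cloud_cover": np.repeat(cloud, 24),
            "wind_speed": np.repeat(wind, 24),
            "pressure_hpa": np.repeat(pressure, 24),
            "pm25": np.repeat(pm25, 24),
        }
    )
    return out


@dataclass
class SimConfig:
    """Study conditions for a synthetic cohort.

    Effects are percentages of the subject mean and combine additively inside
    a multiplicative factor: AHI = mean * (1 + total%/100) * noise.
    ``temp_effect`` / ``tst_effect`` are slopes (% per degC relative to
    ``temp_ref_c``; % per minute of TST deviation) or arbitrary callables.
    """

    n_participants: int = 500
    years: tuple[int, ...] = (2021, 2022)
    latitude_band: str = "30..90"
    n_locations: int = 4
    seasonal_amplitude: float = 5.0       # % AHI change, half peak-to-trough
    seasonal_phase: float = 199.0         # day-of-year of the seasonal peak
    temp_effect: float | object = 0.0     # % per degC, or callable degC -> %
    temp_ref_c: float = 11.0
    tst_effect: float | object = 0.0      # % per minute, or callable min -> %
    dow_effects: tuple[float, ...] = (0.0,) * 7
    mean_ahi_log_mu: float = 2.6539       # log-normal matched to mean 18, SD 14
    mean_ahi_log_sigma: float = 0.6878
    min_mean_ahi: float = 5.0             # inclusion floor (at least mild OSA)
    night_cv: float = 0.50                # within-subject coefficient of variation
    habitual_tst_mean_min: float = 438.0  # 7.3 h cohort mean sleep duration
    habitual_tst_sd_min: float = 45.0
    tst_night_sd_min: float = 60.0
    winter_tst_lengthening_min: float = 15.0
    onset_mean_min: float = 270.0         # 22:30, minutes after 18:00
    onset_between_sd_min: float = 40.0
    onset_night_sd_min: float = 30.0
    adherence: float = 5.5                # target mean recordings per week
    missing_night_prob: float = 0.05
    seed: int = 0
    exposure_params: ExposureParams = field(default_factory=ExposureParams)

    def __post_init__(self):
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        if self.night_cv < 0:
            raise ValueError("night_cv must be >= 0")
        if not 1 <= self.seasonal_phase <= 365:
            raise ValueError("seasonal_phase must be in [1, 365]")
        if self.latitude_band not in LATITUDE_BANDS:
            raise ValueError(
                f"latitude_band must be one of {sorted(LATITUDE_BANDS)}"
            )

    @property
    def latitude(self) -> float:
        return LATITUDE_BANDS[self.latitude_band]

    def seasonal_curve(self, days=None) -> np.ndarray:
        """Injected seasonal effect (% AHI change) over day-of-year; mean zero."""
        if days is None:
            days = np.arange(1, 366)
        days = np.asarray(days, dtype=float)
        return self.seasonal_amplitude * np.cos(
            2 * np.pi * (days - self.seasonal_phase) / 365.0
        )

    def temp_effect_pct(self, temp_c) -> np.ndarray:
        if callable(self.temp_effect):
            return np.asarray(self.temp_effect(np.asarray(temp_c, dtype=float)))
        return float(self.temp_effect) * (np.asarray(temp_c, dtype=float) - self.temp_ref_c)

    def tst_effect_pct(self, delta_min) -> np.ndarray:
        if callable(self.tst_effect):
            return np.asarray(self.tst_effect(np.asarray(delta_min, dtype=float)))
        return float(self.tst_effect) * np.asarray(delta_min, dtype=float)


@dataclass
class SimTruth:
    """Everything injected into a simulated cohort, for parameter recovery."""

    seasonal_curve: np.ndarray            # % change, days 1..365
    seasonal_peak_trough: float           # max - min of the injected curve
    temp_effect_desc: str
    tst_effect_desc: str
    dow_effects: tuple[float, ...]
    subject_mean_ahi: dict[str, float]
    config: dict

    def to_dict(self) -> dict:
        return {
            "seasonal_curve": self.seasonal_curve.tolist(),
            "seasonal_peak_trough": self.seasonal_peak_trough,
            "temp_effect": self.temp_effect_desc,
            "tst_effect": self.tst_effect_desc,
            "dow_effects": list(self.dow_effects),
            "subject_mean_ahi": self.subject_mean_ahi,
            "config": self.config,
        }


def default_locations(config: SimConfig) -> pd.DataFrame:
    """Deterministic location roster for a band: ids, latitudes, cycle offsets."""
    lat0 = config.latitude
    rows = []
    for i in range(config.n_locations):
        params = ExposureParams(
            temp_mean_c=config.exposure_params.temp_mean_c + 2.0 * (i - (config.n_locations - 1) / 2),
            temp_seasonal_amp_c=config.exposure_params.temp_seasonal_amp_c,
            temp_diurnal_amp_c=config.exposure_params.temp_diurnal_amp_c,
            temp_noise_sd_c=config.exposure_params.temp_noise_sd_c,
            summer_peak_doy=config.exposure_params.summer_peak_doy,
        )
        rows.append({"location_id": f"L{i:02d}", "latitude": lat0, "params": params})
    return pd.DataFrame(rows)


def simulate_band_exposures(config: SimConfig) -> pd.DataFrame:
    """Hourly exposures for every location in the configured band."""
    locs = default_locations(config)
    frames = [
        simulate_exposures(
            r.location_id, r.latitude, config.years, r.params,
            seed=(config.seed * 1000 + 7 * i + 1) % (2**31),
        )
        for i, r in enumerate(locs.itertuples())
    ]
    return pd.concat(frames, ignore_index=True)


def simulate_cohort(
    config: SimConfig, exposures: pd.DataFrame
) -> tuple[pd.DataFrame, SimTruth]:
    """Generate nightly records under the configured truth.

    ``exposures`` is an hourly table covering every location-date the cohort
    needs (see :func:`simulate_band_exposures`).  Returns the long nightly
    table (participant_id, date, location_id, ahi, tst_min, onset_min) and
    the :class:`SimTruth` sidecar.
    """
    rng = np.random.default_rng(config.seed)
    daily = daily_average(exposures)
    locations = np.sort(daily["location_id"].unique())
    dates = _dates_for_years(config.years)
    n_days = len(dates)

    # exposure coverage check: every location must cover every simulated date
    temp_by_loc = {}
    for loc in locations:
        sub = daily[daily["location_id"] == loc].set_index("date")["temp_c"]
        sub = sub.reindex(dates)
        if sub.isna().any():
            gap = dates[sub.isna().to_numpy()][0]
            raise ValueError(
                f"exposures missing for location {loc!r} on {gap.date()}"
            )
        temp_by_loc[loc] = sub.to_numpy()

    P = config.n_participants
    ids = np.array([f"P{i:05d}" for i in range(P)])
    truth_conf = dataclasses.asdict(config)
    truth_conf["exposure_params"] = dataclasses.asdict(config.exposure_params)
    truth_conf["temp_effect"] = (
        "callable" if callable(config.temp_effect) else config.temp_effect
    )
    truth_conf["tst_effect"] = (
        "callable" if callable(config.tst_effect) else config.tst_effect
    )
    curve = config.seasonal_curve()
    make_truth = lambda means: SimTruth(
        seasonal_curve=curve,
        seasonal_peak_trough=float(curve.max() - curve.min()),
        temp_effect_desc=(
            "callable" if callable(config.temp_effect)
            else f"{config.temp_effect} % per degC about {config.temp_ref_c} degC"
        ),
        tst_effect_desc=(
            "callable" if callable(config.tst_effect)
            else f"{config.tst_effect} % per minute of TST deviation"
        ),
        dow_effects=tuple(config.dow_effects),
        subject_mean_ahi=means,
        config=truth_conf,
    )
    empty = pd.DataFrame(
        columns=["participant_id", "date", "location_id", "ahi", "tst_min", "onset_min"]
    )
    if P == 0:
        return empty, make_truth({})

    # subject-level draws
    means = np.exp(rng.normal(config.mean_ahi_log_mu, config.mean_ahi_log_sigma, P))
    for _ in range(100):
        low = means < config.min_mean_ahi
        if not low.any():
            break
        means[low] = np.exp(
            rng.normal(config.mean_ahi_log_mu, config.mean_ahi_log_sigma, int(low.sum()))
        )
    means = np.maximum(means, config.min_mean_ahi)
    habitual_tst = rng.normal(config.habitual_tst_mean_min, config.habitual_tst_sd_min, P)
    habitual_onset = rng.normal(config.onset_mean_min, config.onset_between_sd_min, P)
    loc_idx = np.arange(P) % len(locations)
    loc_of_p = locations[loc_idx]

    doy = day_of_year(dates)
    dow = dates.dayofweek.to_numpy()  # 0 = Monday

    p_night = min(1.0, config.adherence / 7.0) * (1.0 - config.missing_night_prob)
    recorded = rng.random((P, n_days)) < p_night

    winter_peak = (config.seasonal_phase + 365.0 / 2) % 365.0
    tst_seasonal = config.winter_tst_lengthening_min * np.cos(
        2 * np.pi * (doy - winter_peak) / 365.0
    )
    tst = (
        habitual_tst[:, None]
        + tst_seasonal[None, :]
        + rng.normal(0.0, config.tst_night_sd_min, (P, n_days))
    )
    tst = np.maximum(tst, 60.0)
    onset = habitual_onset[:, None] + rng.normal(0.0, config.onset_night_sd_min, (P, n_days))

    temp = np.stack([temp_by_loc[loc] for loc in loc_of_p])  # (P, n_days)
    pct = (
        config.seasonal_curve(doy)[None, :]
        + config.temp_effect_pct(temp)
        + config.tst_effect_pct(tst - habitual_tst[:, None])
        + np.asarray(config.dow_effects, dtype=float)[dow][None, :]
    )
    if config.night_cv > 0:
        shape = 1.0 / config.night_cv**2
        noise = rng.gamma(shape, 1.0 / shape, (P, n_days))
    else:
        noise = np.ones((P, n_days))
    ahi = means[:, None] * np.maximum(1.0 + pct / 100.0, 0.0) * noise

    pi, di = np.nonzero(recorded)
    records = pd.DataFrame(
        {
            "participant_id": ids[pi],
            "date": dates[di],
            "location_id": loc_of_p[pi],
            "ahi": ahi[pi, di],
            "tst_min": tst[pi, di],
            "onset_min": onset[pi, di],
        }
    )
    truth = make_truth({ids[i]: float(means[i]) for i in range(P)})
    return records, truth
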