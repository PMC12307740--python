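"""Derived nightly variables.

The analysis outcome is the within-person, within-year relative AHI change

    cAHI = 100 * (AHI_night - AHI_yearly_mean) / AHI_yearly_mean   [%]

which makes nights comparable across severities (a +50% night means the same
thing for a mild and a severe sleeper).  This module also computes nightly
sleep deviations (delta TST / delta TIB in minutes from the yearly mean),
relative humidity from air and dew-point temperature, 24 h exposure means,
and the night-to-exposure join.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: exposure variables carried on the daily table
EXPOSURE_VARS = ["temp_c", "dewpoint_c", "cloud_cover", "wind_speed", "pressure_hpa", "pm25"]

# Magnus saturation-vapour-pressure constants (Alduchov-Eskridge fit)
_MAGNUS_A = 17.625
_MAGNUS_B = 243.04  # degC


def ahi_change(ahi_night, yearly_mean):
    """Relative AHI change of a night versus the participant's yearly mean, in %.

    ``100 * (ahi_night - yearly_mean) / yearly_mean``.  Requires a strictly
    positive yearly mean (retained participant-years always have mean >= 5).
    """
    ahi_night = np.asarray(ahi_night, dtype=float)
    yearly_mean = np.asarray(yearly_mean, dtype=float)
    if np.any(yearly_mean <= 0):
        raise ValueError("yearly mean AHI must be > 0 to express relative change")
    return 100.0 * (ahi_night - yearly_mean) / yearly_mean


def relative_humidity(temp_c, dewpoint_c):
    """Relative humidity (%) from air and dew-point temperature (degC).

    Magnus form: RH = 100 * e(dewpoint) / e(temp) with
    e(T) = exp(17.625 T / (243.04 + T)).  Values above 100 (dew point above
    air temperature, possible in noisy gridded products) are clipped to 100
    with a warning.
    """
    t = np.asarray(temp_c, dtype=float)
    td = np.asarray(dewpoint_c, dtype=float)
    rh = 100.0 * np.exp(_MAGNUS_A * td / (_MAGNUS_B + td) - _MAGNUS_A * t / (_MAGNUS_B + t))
    n_clip = int(np.sum(rh > 100.0))
    if n_clip:
        warnings.warn(
            f"relative humidity exceeded 100% for {n_clip} value(s) "
            "(dew point above air temperature); clipping to 100",
            stacklevel=2,
        )
        rh = np.minimum(rh, 100.0)
    if rh.ndim == 0:
        return float(rh)
    return rh


def day_of_year(dates) -> np.ndarray:
    """Day-of-year on the 1..365 spline domain; Feb 29 maps to 59 (same as Feb 28).

    In leap years every day from Mar 1 onward has its ordinal shifted down by
    one so the domain stays 1..365 across years.
    """
    dates = pd.DatetimeIndex(dates)
    doy = dates.dayofyear.to_numpy().copy()
    leap = dates.is_leap_year
    after_feb28 = doy >= 60
    doy = np.where(leap & after_feb28, doy - 1, doy)
    return doy.astype(int)


def delta_sleep(records: pd.DataFrame, summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-night deviations of TST and onset from the participant-year mean.

    Adds ``delta_tst`` and ``delta_tib`` (minutes).  Every participant-year in
    ``records`` must be covered by ``summaries``; deviations are taken from
    the *observed* valid-night means so they average to zero by construction.
    """
    rec = records.copy()
    rec["year"] = pd.DatetimeIndex(rec["date"]).year
    key = ["participant_id", "year"]
    missing = (
        rec[key].drop_duplicates().merge(summaries[key], on=key, how="left", indicator=True)
    )
    gaps = missing[missing["_merge"] == "left_only"]
    if len(gaps):
        first = gaps.iloc[0]
        raise ValueError(
            f"no participant-year summary for ({first['participant_id']}, {first['year']})"
        )
    means = summaries.set_index(key)
    rec = rec.join(
        means[["habitual_tst_h", "mean_onset_min"]], on=key, how="left"
    )
    rec["delta_tst"] = rec["tst_min"] - rec["habitual_tst_h"] * 60.0
    rec["delta_tib"] = rec["onset_min"] - rec["mean_onset_min"]
    return rec.drop(columns=["habitual_tst_h", "mean_onset_min"])


def daily_average(hourly: pd.DataFrame, min_hours: int = 18) -> pd.DataFrame:
    """24 h means per location-date from an hourly exposure table.

    Days with fewer than ``min_hours`` of the 24 hours present are kept but
    their exposure values are set to missing.  Relative humidity is derived
    from the daily temperature / dew-point means.
    """
    h = hourly.copy()
    ts = pd.DatetimeIndex(h["timestamp"])
    h["date"] = ts.normalize()
    grouped = h.groupby(["location_id", "date"], sort=True)
    out = grouped[EXPOSURE_VARS].mean()
    out["n_hours"] = grouped.size()
    incomplete = out["n_hours"] < min_hours
    if incomplete.any():
        logger.info("daily_average: %d location-days with <%d hours marked missing",
                    int(incomplete.sum()), min_hours)
        out.loc[incomplete, EXPOSURE_VARS] = np.nan
    out = out.reset_index()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clipping noted once at hourly source
        out["rh_pct"] = relative_humidity(out["temp_c"], out["dewpoint_c"])
    return out


def match_exposures(nights: pd.DataFrame, daily: pd.DataFrame) -> pd.DataFrame:
    """Join each night to the 24 h exposure means of its onset calendar date.

    Nights whose date has no exposure row keep missing exposure fields (models
    that need them drop those nights themselves).  A location id absent from
    the exposure table altogether is an error.
    """
    known = set(daily["location_id"].unique())
    used = set(nights["location_id"].unique())
    unknown = sorted(used - known)
    if unknown:
        raise ValueError(f"unknown location_id in nightly records: {unknown[0]!r}")
    d = daily.copy()
    d["date"] = pd.DatetimeIndex(d["date"]).normalize()
    n = nights.copy()
    n["date"] = pd.DatetimeIndex(n["date"]).normalize()
    cols = ["location_id", "date"] + EXPOSURE_VARS + ["rh_pct"]
    merged = n.merge(d[cols], on=["location_id", "date"], how="left")
    n_miss = int(merged["temp_c"].isna().sum())
    if n_miss:
        logger.info("match_exposures: %d night(s) without matched exposures", n_miss)
    return merged


def derive_nights(
    records: pd.DataFrame,
    summaries: pd.DataFrame,
    daily_exposures: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the analysis-ready nightly table.

    Input ``records`` should already be restricted to valid nights of retained
    participant-years (see :mod:`osaclim.qc`).  Adds cAHI, sleep deviations,
    day-of-year / day-of-week, participant-year irregularity covariates, and
    (optionally) matched daily exposures.
    """
    rec = delta_sleep(records, summaries)
    key = ["participant_id", "year"]
    cols = ["yearly_mean_ahi", "tst_irregularity", "timing_irregularity", "severity"]
    rec = rec.join(summaries.set_index(key)[cols], on=key, how="left")
    rec["c_ahi"] = ahi_change(rec["ahi"], rec["yearly_mean_ahi"])
    dates = pd.DatetimeIndex(rec["date"])
    rec["day_of_year"] = day_of_year(dates)
    rec["day_of_week"] = dates.dayofweek.to_numpy() + 1  # 1 = Monday .. 7 = Sunday
    if daily_exposures is not None:
        rec = match_exposures(rec, daily_exposures)
    return rec
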