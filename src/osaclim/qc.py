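"""Cohort inclusion rules and participant-year summaries.

Regular-use criteria for home multi-night monitoring: a participant-year is
analysed only if the device was used on average >= 4 nights per active week
and produced >= 28 valid AHI nights in the year, and only participant-years
with a yearly mean AHI >= 5 events/h (at least mild OSA) are retained.  A
night is valid when total sleep time is at least 5 h — the AHI cannot be
reliably estimated on shorter nights; shorter nights still count as device
use for the adherence rule but never enter AHI statistics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_VALID_TST_MIN = 300.0      # >= 5 h sleep: AHI estimable (inclusive boundary)
MIN_VALID_NIGHTS = 28          # valid AHI nights per year
MIN_RECORDINGS_PER_WEEK = 4.0  # mean recordings per active week
MIN_YEARLY_AHI = 5.0           # at least mild OSA

#: severity bands on the yearly mean AHI (events/h): mild [5, 15),
#: moderate [15, 30], severe > 30.
SEVERITY_BINS = {"mild": (5.0, 15.0), "moderate": (15.0, 30.0), "severe": (30.0, np.inf)}

TST_BIN_EDGES_H = [0.0, 6.0, 7.0, 8.0, 9.0, np.inf]
TST_BIN_LABELS = ["<6", "6-7", "7-8", "8-9", "9+"]


def severity_class(yearly_mean_ahi) -> np.ndarray:
    """OSA severity from the yearly mean AHI: mild [5,15), moderate [15,30], severe >30."""
    m = np.asarray(yearly_mean_ahi, dtype=float)
    out = np.where(m > 30.0, "severe", np.where(m >= 15.0, "moderate", "mild"))
    return out if out.ndim else out[()]


def flag_valid_nights(records: pd.DataFrame) -> pd.DataFrame:
    """Add a ``valid`` flag: True iff TST >= 5 h (300 min, inclusive)."""
    rec = records.copy()
    rec["valid"] = rec["tst_min"] >= MIN_VALID_TST_MIN
    return rec


def _participant_year_stats(rec: pd.DataFrame) -> pd.DataFrame:
    rec = rec.copy()
    rec["year"] = pd.DatetimeIndex(rec["date"]).year
    g = rec.groupby(["participant_id", "year"], sort=True)
    stats = pd.DataFrame(
        {
            "n_recordings": g.size(),
            "n_valid_nights": g["valid"].sum().astype(int),
            "first_date": g["date"].min(),
            "last_date": g["date"].max(),
        }
    )
    span_days = (stats["last_date"] - stats["first_date"]).dt.days
    stats["active_weeks"] = span_days // 7 + 1
    stats["recordings_per_week"] = stats["n_recordings"] / stats["active_weeks"]
    return stats


def filter_regular_users(records: pd.DataFrame) -> pd.DataFrame:
    """Keep nights of participant-years meeting both regular-use rules.

    Adherence counts every recording (including invalid short nights); the
    valid-night floor counts only nights with estimable AHI.  Idempotent.
    """
    rec = flag_valid_nights(records) if "valid" not in records.columns else records.copy()
    stats = _participant_year_stats(rec)
    keep = stats[
        (stats["recordings_per_week"] >= MIN_RECORDINGS_PER_WEEK)
        & (stats["n_valid_nights"] >= MIN_VALID_NIGHTS)
    ]
    rec["year"] = pd.DatetimeIndex(rec["date"]).year
    out = rec.merge(
        keep.reset_index()[["participant_id", "year"]],
        on=["participant_id", "year"],
        how="inner",
    )
    logger.info(
        "filter_regular_users: retained %d/%d participant-years (%d/%d nights)",
        len(keep), len(stats), len(out), len(rec),
    )
    return out


def summarize_participant_year(records: pd.DataFrame) -> pd.DataFrame:
    """Per participant-year summaries over valid nights.

    Returns one row per retained participant-year with the yearly mean/SD AHI,
    within-year coefficient of variation (%), habitual sleep duration, sleep
    duration and timing irregularity (within-year SDs, minutes) and the OSA
    severity class.  Participant-years with yearly mean AHI < 5 are dropped.
    """
    rec = flag_valid_nights(records) if "valid" not in records.columns else records.copy()
    rec["year"] = pd.DatetimeIndex(rec["date"]).year
    valid = rec[rec["valid"]]
    if not len(valid):
        raise ValueError("empty participant-year: no valid nights to summarize")
    g = valid.groupby(["participant_id", "year"], sort=True)
    out = pd.DataFrame(
        {
            "yearly_mean_ahi": g["ahi"].mean(),
            "yearly_sd_ahi": g["ahi"].std(ddof=1).fillna(0.0),
            "n_valid_nights": g.size(),
            "habitual_tst_h": g["tst_min"].mean() / 60.0,
            "tst_irregularity": g["tst_min"].std(ddof=1).fillna(0.0),
            "mean_onset_min": g["onset_min"].mean(),
            "timing_irregularity": g["onset_min"].std(ddof=1).fillna(0.0),
        }
    )
    out["cv"] = 100.0 * out["yearly_sd_ahi"] / out["yearly_mean_ahi"]
    n_sub5 = int((out["yearly_mean_ahi"] < MIN_YEARLY_AHI).sum())
    if n_sub5:
        logger.info("summarize_participant_year: dropping %d participant-years with "
                    "yearly mean AHI < %g", n_sub5, MIN_YEARLY_AHI)
    out = out[out["yearly_mean_ahi"] >= MIN_YEARLY_AHI]
    out["severity"] = severity_class(out["yearly_mean_ahi"].to_numpy())
    return out.reset_index()


def assign_subgroups(
    summaries: pd.DataFrame, demographics: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Attach subgroup labels: habitual-TST bins, decadal age bins, sex.

    ``demographics`` is an optional table keyed by ``participant_id`` with
    ``age`` and/or ``sex``; participants without a row get label ``unknown``
    and are excluded from that subgroup analysis only (not from main fits).
    """
    out = summaries.copy()
    out["tst_bin"] = pd.cut(
        out["habitual_tst_h"], bins=TST_BIN_EDGES_H, labels=TST_BIN_LABELS, right=False
    ).astype(str)
    if demographics is not None:
        demo = demographics.drop_duplicates("participant_id").set_index("participant_id")
        out = out.join(demo, on="participant_id", how="left")
    for col in ("age", "sex"):
        if col not in out.columns:
            out[col] = np.nan
    age = pd.to_numeric(out["age"], errors="coerce")
    lo = (age // 10 * 10).astype("Int64")
    out["age_bin"] = np.where(
        age.notna(), lo.astype(str) + "-" + (lo + 10).astype(str), "unknown"
    )
    out["sex"] = out["sex"].fillna("unknown")
    out = out.drop(columns=["age"])
    return out
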