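"""End-to-end orchestration: simulate/load -> QC -> derive -> fit -> report.

One :class:`~osaclim.io.RunConfig` drives the whole analysis: per group a
baseline model (seasonal spline + day-of-week) and a fully adjusted model
(plus confounder splines), a minimally vs fully adjusted model pair per
exposure of interest, seasonal curves with peak-to-trough deltas, percentile
contrasts, sensitivity refits (seasonal df sweep, date restriction, binary
outcomes), and a manifest.  Every stochastic step is seeded from the config,
so identical configurations reproduce byte-identical result bundles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import effects, qc, transforms
from .io import RunConfig, read_exposures, read_nightly, write_outputs
from .model import FixedEffectsSplineModel, ModelFit
from .simulate import SimConfig, simulate_band_exposures, simulate_cohort

logger = logging.getLogger(__name__)

#: per-exposure confounder sets for the fully adjusted exposure models.
#: Each exposure is adjusted for the remaining nightly-varying environmental
#: terms (an editable mapping; transcribe a study-specific one if needed).
DEFAULT_EXPOSURE_CONFOUNDERS = {
    "temp_c": ["cloud_cover", "rh_pct", "wind_speed", "pressure_hpa", "pm25"],
    "pressure_hpa": ["temp_c", "cloud_cover", "rh_pct", "wind_speed", "pm25"],
    "wind_speed": ["temp_c", "cloud_cover", "rh_pct", "pressure_hpa", "pm25"],
    "pm25": ["temp_c", "cloud_cover", "rh_pct", "wind_speed", "pressure_hpa"],
    "rh_pct": ["temp_c", "cloud_cover", "wind_speed", "pressure_hpa", "pm25"],
    "cloud_cover": ["temp_c", "rh_pct", "wind_speed", "pressure_hpa", "pm25"],
    "delta_tst": ["temp_c", "cloud_cover", "rh_pct", "wind_speed", "pressure_hpa", "pm25"],
    "delta_tib": ["temp_c", "cloud_cover", "rh_pct", "wind_speed", "pressure_hpa", "pm25"],
}


@dataclass
class AdjustmentComparison:
    """Minimal vs fully adjusted EMM curves for one exposure term."""

    term: str
    max_divergence: float
    curve_range: float
    within_ci: bool
    collinearity_suspected: bool

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "max_divergence": self.max_divergence,
            "curve_range": self.curve_range,
            "within_ci": self.within_ci,
            "collinearity_suspected": self.collinearity_suspected,
        }


def compare_adjustment(
    fit_min: ModelFit,
    fit_full: ModelFit,
    term: str,
    data: pd.DataFrame,
    fraction: float = 0.25,
    n_grid: int = 50,
) -> AdjustmentComparison:
    """Divergence between minimally and fully adjusted exposure-response curves.

    Both fits must carry ``term``.  Curves are compared over an interior grid
    (1st..99th percentile of the pooled exposure), referenced at the median;
    a maximum divergence above ``fraction`` of the larger curve's range flags
    suspected collinearity.
    """
    x = pd.to_numeric(data[term], errors="coerce").dropna().to_numpy()
    grid = np.linspace(np.percentile(x, 1), np.percentile(x, 99), n_grid)
    ref = float(np.percentile(x, 50))
    c_min = effects.emm_curve(fit_min, term, grid, ref)
    c_full = effects.emm_curve(fit_full, term, grid, ref)
    diff = np.abs(c_min["estimate"].to_numpy() - c_full["estimate"].to_numpy())
    rng_ = max(
        float(c_min["estimate"].max() - c_min["estimate"].min()),
        float(c_full["estimate"].max() - c_full["estimate"].min()),
    )
    within = bool(
        np.all(
            (c_min["estimate"] >= c_full["ci_low"]) & (c_min["estimate"] <= c_full["ci_high"])
        )
        and np.all(
            (c_full["estimate"] >= c_min["ci_low"]) & (c_full["estimate"] <= c_min["ci_high"])
        )
    )
    max_div = float(diff.max())
    flagged = rng_ > 0 and max_div > fraction * rng_
    if flagged:
        logger.warning("compare_adjustment: collinearity suspected for %s "
                       "(divergence %.3g vs range %.3g)", term, max_div, rng_)
    return AdjustmentComparison(term, max_div, rng_, within, flagged)


def _load_inputs(config: RunConfig):
    if config.nightly_path:
        records = read_nightly(config.nightly_path)
        exposures = read_exposures(config.exposures_path) if config.exposures_path else None
        truth = None
    else:
        sim = SimConfig(**{**config.simulate, "seed": config.seed})
        exposures = simulate_band_exposures(sim)
        records, truth = simulate_cohort(sim, exposures)
        exposures.attrs["granularity"] = "hourly"
    return records, exposures, truth


def prepare(config: RunConfig):
    """Load or simulate, QC, and derive the analysis-ready nightly table."""
    records, exposures, truth = _load_inputs(config)
    flagged = qc.flag_valid_nights(records)
    retained = qc.filter_regular_users(flagged)
    summaries = qc.summarize_participant_year(retained)
    summaries = qc.assign_subgroups(summaries)
    valid = retained[retained["valid"]].merge(
        summaries[["participant_id", "year"]], on=["participant_id", "year"]
    )
    daily = None
    if exposures is not None:
        daily = (
            transforms.daily_average(exposures)
            if exposures.attrs.get("granularity", "hourly") == "hourly"
            else exposures.rename(columns={"timestamp": "date"})
        )
    nights = transforms.derive_nights(valid, summaries, daily)
    if config.date_restriction:
        cutoff = pd.Timestamp(config.date_restriction)
        before = len(nights)
        nights = nights[nights["date"] >= cutoff]
        logger.info("date restriction %s: %d -> %d nights", config.date_restriction,
                    before, len(nights))
    return nights, summaries, truth


def _groups(nights: pd.DataFrame, config: RunConfig):
    if config.grouping == "pooled":
        yield "pooled", nights
    elif config.grouping == "location":
        for loc, sub in nights.groupby("location_id", sort=True):
            if sub["participant_id"].nunique() >= config.min_group_users:
                yield str(loc), sub
            else:
                logger.info("group %s skipped: fewer than %d users", loc,
                            config.min_group_users)
    else:
        raise ValueError(f"unknown grouping {config.grouping!r}")


def _available_confounders(nights: pd.DataFrame, wanted, df: int):
    out = []
    for v in wanted:
        if v in nights.columns and pd.to_numeric(nights[v], errors="coerce").notna().any():
            out.append((v, df))
        else:
            logger.info("confounder %s unavailable; skipped", v)
    return out


def run(config: RunConfig) -> dict:
    """Execute the full analysis plan; write the bundle; return the results dict."""
    nights, summaries, truth = prepare(config)
    results: dict = {}
    curves_rows, contrast_rows, compare_rows, fit_meta = [], [], [], []
    seed = config.seed

    for gname, gnights in _groups(nights, config):
        confs = _available_confounders(gnights, config.confounders, config.confounder_df)
        baseline = FixedEffectsSplineModel(seasonal_df=config.seasonal_df).fit(gnights)
        full = FixedEffectsSplineModel(
            seasonal_df=config.seasonal_df, confounders=confs
        ).fit(gnights)

        for label, fit in (("baseline", baseline.result_), ("full", full.result_)):
            sc = effects.peak_trough(
                fit, reference=float(config.reference_doy),
                n_draws=config.peak_trough_draws, seed=seed,
            )
            df_c = sc.frame()
            df_c.insert(0, "group", gname)
            df_c.insert(1, "model", label)
            curves_rows.append(df_c)
            contrast_rows.append({
                "group": gname, "model": label, "term": "day_of_year",
                "contrast": "peak vs trough", "estimate": sc.delta,
                "ci_low": sc.delta_ci[0], "ci_high": sc.delta_ci[1],
                "setting_hi": sc.peak_day, "setting_lo": sc.trough_day,
            })
            fit_meta.append({
                "group": gname, "model": label, "n_obs": fit.n_obs,
                "n_strata": fit.n_strata, "n_users": gnights["participant_id"].nunique(),
                "dropped_columns": ",".join(fit.dropped),
            })

        # per-exposure minimally vs fully adjusted pair
        for term in config.exposures:
            if term not in gnights.columns or gnights[term].isna().all():
                logger.info("exposure %s unavailable in group %s; skipped", term, gname)
                continue
            fit_min = FixedEffectsSplineModel(
                seasonal_df=config.seasonal_df,
                confounders=[(term, config.confounder_df)],
            ).fit(gnights)
            adj = [
                (v, config.confounder_df)
                for v in DEFAULT_EXPOSURE_CONFOUNDERS.get(term, [])
                if v in gnights.columns and gnights[v].notna().any()
            ]
            fit_full = FixedEffectsSplineModel(
                seasonal_df=config.seasonal_df,
                confounders=[(term, config.confounder_df)] + adj,
            ).fit(gnights)
            for label, f in (("minimal", fit_min.result_), ("full", fit_full.result_)):
                for p_hi, p_lo in ((75, 25), (95, 50), (5, 50)):
                    cr = effects.percentile_contrast(f, term, gnights, p_hi, p_lo)
                    contrast_rows.append({
                        "group": gname, "model": label, "term": term,
                        "contrast": cr.reference, "estimate": cr.estimate,
                        "ci_low": cr.ci_low, "ci_high": cr.ci_high,
                        "setting_hi": cr.setting_hi, "setting_lo": cr.setting_lo,
                    })
            comp = compare_adjustment(
                fit_min.result_, fit_full.result_, term, gnights,
                fraction=config.collinearity_fraction,
            )
            compare_rows.append({"group": gname, **comp.to_dict()})

        if config.df_sweep:
            for df_s in (4, 6, 8):
                fit_s = FixedEffectsSplineModel(seasonal_df=df_s).fit(gnights)
                sc = effects.peak_trough(
                    fit_s.result_, reference=float(config.reference_doy),
                    n_draws=config.peak_trough_draws, seed=seed,
                )
                df_c = sc.frame()
                df_c.insert(0, "group", gname)
                df_c.insert(1, "model", f"df{df_s}")
                curves_rows.append(df_c)

        if config.binary_outcomes:
            for thr in (15, 30):
                try:
                    fit_b = FixedEffectsSplineModel(
                        outcome="binary", binary_threshold=thr,
                        seasonal_df=config.seasonal_df,
                        max_per_stratum=config.binary_max_per_stratum,
                        random_state=seed,
                    ).fit(gnights)
                except ValueError as e:
                    logger.info("binary outcome %s in group %s skipped: %s",
                                thr, gname, e)
                    continue
                sc = effects.peak_trough(
                    fit_b.result_, reference=float(config.reference_doy),
                    n_draws=config.peak_trough_draws, seed=seed,
                )
                oc = effects.odds_change(
                    fit_b.result_, "day_of_year",
                    float(sc.peak_day), float(sc.trough_day),
                )
                contrast_rows.append({
                    "group": gname, "model": f"binary{thr}", "term": "day_of_year",
                    "contrast": "odds % change, peak vs trough",
                    "estimate": oc.estimate, "ci_low": oc.ci_low,
                    "ci_high": oc.ci_high,
                    "setting_hi": sc.peak_day, "setting_lo": sc.trough_day,
                })

    results["seasonal_curves"] = pd.concat(curves_rows, ignore_index=True)
    results["contrasts"] = pd.DataFrame(contrast_rows)
    if compare_rows:
        results["adjustment_comparison"] = pd.DataFrame(compare_rows)
    results["fits"] = pd.DataFrame(fit_meta)
    results["cohort_summary"] = summaries.drop(columns=["first_date", "last_date"],
                                               errors="ignore")
    if truth is not None:
        results["sim_truth"] = truth.to_dict()
    write_outputs(results, config.outdir, config=config, seed=config.seed)
    return results
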