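"""Reading and writing the pipeline's tabular formats.

All interchange is delimited text (CSV): nightly records, hourly or daily
exposure series, derived tables, curves and contrasts.  Readers validate the
schema strictly — malformed rows are rejected with row-numbered diagnostics,
structural problems (missing columns, duplicate participant-nights) raise.
The writer produces byte-stable output plus a manifest (config hash, seed,
row counts, file digests) so a rerun with the same configuration reproduces
identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

NIGHTLY_COLUMNS = {
    "participant_id": "participant_id",
    "date": "date",
    "location_id": "location_id",
    "ahi": "ahi",
    "tst_min": "tst_min",
    "onset_min_after_18h": "onset_min",
}

EXPOSURE_VALUE_COLUMNS = ["temp_c", "dewpoint_c", "cloud_cover", "wind_speed",
                          "pressure_hpa", "pm25"]

FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of one pipeline run (see ``osaclim --help``)."""

    outdir: str = "osaclim_out"
    seed: int = 0
    # inputs: either paths to tables, or "simulate" settings used by the CLI
    nightly_path: str | None = None
    exposures_path: str | None = None
    demographics_path: str | None = None
    simulate: dict = field(default_factory=dict)
    # model settings
    outcome: str = "c_ahi"            # c_ahi | ahi | binary15 | binary30
    seasonal_df: int = 8
    confounder_df: int = 4
    confounders: list[str] = field(default_factory=lambda: [
        "cloud_cover", "rh_pct", "pm25", "wind_speed", "pressure_hpa",
        "tst_irregularity", "timing_irregularity",
    ])
    exposures: list[str] = field(default_factory=lambda: [
        "temp_c", "pressure_hpa", "wind_speed", "delta_tst",
    ])
    reference_doy: int = 172          # June 21
    grouping: str = "pooled"          # pooled | latitude_band | location
    min_group_users: int = 200
    subgroups: list[str] = field(default_factory=list)  # e.g. ["sex", "severity"]
    robust: bool = False              # cluster-robust covariance by participant
    # sensitivity toggles
    df_sweep: bool = False            # refit seasonal term at df 4, 6, 8
    date_restriction: str | None = None   # e.g. "2022-09-01": keep nights on/after
    binary_outcomes: bool = False     # conditional-logistic fits at AHI >= 15 / 30
    binary_max_per_stratum: int = 60  # thin long strata before conditional fits
    peak_trough_draws: int = 10000
    collinearity_fraction: float = 0.25

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        """Stable digest of the configuration (output dir excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _reject(df: pd.DataFrame, bad: pd.Series, reason: str, rejected: list) -> pd.DataFrame:
    idx = df.index[bad]
    for i in idx[:20]:
        rejected.append((int(i) + 2, reason))  # +2: 1-based with header row
    if len(idx):
        logger.warning("rejected %d row(s): %s (first at file row %d)",
                       len(idx), reason, int(idx[0]) + 2)
    return df[~bad]


def read_nightly(path: str | Path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a nightly-records CSV.

    ``schema`` maps file column names to the canonical names
    (participant_id, date, location_id, ahi, tst_min, onset_min); by default
    the writer's own column names are expected.  Malformed rows (unparseable
    date, non-finite or negative AHI/TST) are rejected and logged with their
    file row numbers; a duplicate (participant, date) pair is an error.
    """
    raw = pd.read_csv(path, dtype=str)
    mapping = schema or NIGHTLY_COLUMNS
    missing = [c for c in mapping if c not in raw.columns]
    if missing:
        raise ValueError(f"missing required column(s) in {path}: {missing}")
    df = raw[list(mapping)].rename(columns=mapping)
    rejected: list[tuple[int, str]] = []
    df["date"] = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    df = _reject(df, df["date"].isna(), "unparseable date", rejected)
    for col in ("ahi", "tst_min", "onset_min"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        df = _reject(df, ~np.isfinite(df[col]), f"non-numeric {col}", rejected)
    for col in ("ahi", "tst_min"):
        df = _reject(df, df[col] < 0, f"negative {col}", rejected)
    dup = df.duplicated(["participant_id", "date"], keep=False)
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            "duplicate (participant_id, date): "
            f"({first['participant_id']}, {first['date'].date()})"
        )
    logger.info("read_nightly: %d accepted, %d rejected from %s",
                len(df), len(rejected), path)
    df.attrs["n_rejected"] = len(rejected)
    df.attrs["rejected_rows"] = rejected
    return df.reset_index(drop=True)


def read_exposures(path: str | Path) -> pd.DataFrame:
    """Read an exposure CSV, auto-detecting hourly vs daily granularity.

    Hourly tables have multiple timestamps per location-date, daily tables
    exactly one; a mixture is an error.  The result carries
    ``df.attrs["granularity"]`` of ``"hourly"`` or ``"daily"``.
    """
    df = pd.read_csv(path)
    required = ["location_id", "timestamp"] + EXPOSURE_VALUE_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s) in {path}: {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="raise")
    for col in EXPOSURE_VALUE_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    per_day = df.groupby(
        ["location_id", df["timestamp"].dt.normalize()], sort=False
    ).size()
    if (per_day == 1).all():
        gran = "daily"
    elif (per_day > 1).all():
        gran = "hourly"
    else:
        raise ValueError("inconsistent timestamp granularity (mixed hourly/daily)")
    df.attrs["granularity"] = gran
    logger.info("read_exposures: %d rows, granularity=%s from %s", len(df), gran, path)
    return df


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(
    results: dict[str, pd.DataFrame | dict],
    outdir: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> Path:
    """Write result tables/objects plus a manifest; returns the manifest path.

    DataFrames become ``<name>.csv``; dicts become ``<name>.json``.  The
    manifest records the config hash, seed, and per-file row counts and
    digests, and is itself byte-stable for a fixed configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = {}
    for name, obj in sorted(results.items()):
        if isinstance(obj, pd.DataFrame):
            fname = f"{name}.csv"
            _write_csv(obj, outdir / fname)
            n_rows = len(obj)
        else:
            fname = f"{name}.json"
            (outdir / fname).write_text(
                json.dumps(obj, sort_keys=True, indent=1, default=str) + "\n"
            )
            n_rows = len(obj) if hasattr(obj, "__len__") else 1
        entries[fname] = {"rows": n_rows, "sha256": _sha256(outdir / fname)}
    manifest = {
        "config_hash": config.config_hash() if config is not None else None,
        "seed": seed if seed is not None else (config.seed if config else None),
        "files": entries,
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    logger.info("write_outputs: %d file(s) + manifest in %s", len(entries), outdir)
    return mpath
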