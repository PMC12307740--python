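import numpy as np
import pandas as pd
import pytest

import osaclim as oc


def simulate_derived(config: oc.SimConfig) -> tuple[pd.DataFrame, oc.SimTruth]:
    """Full prep path: simulate -> QC -> derived nightly table with exposures."""
    exposures = oc.simulate_band_exposures(config)
    records, truth = oc.simulate_cohort(config, exposures)
    retained = oc.filter_regular_users(oc.flag_valid_nights(records))
    summaries = oc.summarize_participant_year(retained)
    valid = retained[retained["valid"]].merge(
        summaries[["participant_id", "year"]], on=["participant_id", "year"]
    )
    daily = oc.daily_average(exposures)
    return oc.derive_nights(valid, summaries, daily), truth


@pytest.fixture(scope="session")
def small_cohort():
    """60 participants x 1 year, seasonal signal only; shared across tests."""
    cfg = oc.SimConfig(n_participants=60, years=(2021,), seasonal_amplitude=10.0,
                       seed=11)
    nights, truth = simulate_derived(cfg)
    return nights, truth


@pytest.fixture()
def qc_fixture():
    """Hand-built 6-participant cohort with known inclusion-rule violations.

    - ok_dense:   daily valid nights all year               -> retained
    - few_nights: 27 valid nights at a high weekly rate     -> excluded (<28)
    - sparse:     104 nights at 2/week                      -> excluded (<4/wk)
    - low_ahi:    dense user with yearly mean AHI 4.9       -> dropped (<5)
    - short_night: dense user with one 4.9 h night          -> retained,
      that night invalid
    - ok_weekly:  208 nights at exactly 4/week              -> retained
    """
    rows = []

    def add(pid, dates, ahi, tst=480.0):
        for d in dates:
            rows.append({"participant_id": pid, "date": pd.Timestamp(d),
                         "location_id": "L00", "ahi": ahi, "tst_min": tst,
                         "onset_min": 270.0})

    all_year = pd.date_range("2021-01-01", "2021-12-31", freq="D")
    add("ok_dense", all_year, 12.0)
    add("few_nights", pd.date_range("2021-03-01", periods=27, freq="D"), 20.0)
    add("sparse", pd.date_range("2021-01-04", periods=104, freq="3D")[:104], 20.0)
    add("low_ahi", all_year, 4.9)
    add("short_night", all_year[:-1], 15.0)
    rows.append({"participant_id": "short_night", "date": all_year[-1],
                 "location_id": "L00", "ahi": 15.0, "tst_min": 294.0,
                 "onset_min": 270.0})
    # 208 nights at exactly 4 per week: 4 consecutive nights each week
    weeks = pd.date_range("2021-01-04", periods=52, freq="7D")
    dates_4wk = [w + pd.Timedelta(days=k) for w in weeks for k in range(4)]
    add("ok_weekly", dates_4wk, 25.0)
    return pd.DataFrame(rows)
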