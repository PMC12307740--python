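import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import osaclim as oc
from osaclim.model import (FixedEffectsSpec, absorb_strata, build_design,
                           fit_binary, fit_gaussian)


def _random_instance(rng, max_strata=5, max_per=20, max_cov=6):
    """A small strata dataset with enough within-strata degrees of freedom."""
    S = rng.integers(2, max_strata + 1)
    p = rng.integers(1, max_cov + 1)
    rows, labels = [], []
    min_per = max(2, (p + 2 + S) // S + 1)  # keep n - S - p >= 2
    for s in range(S):
        n_s = rng.integers(min_per, max(max_per, min_per) + 1)
        rows.append(rng.normal(size=(n_s, p)))
        labels += [s] * n_s
    X = np.vstack(rows)
    strata = np.array(labels)
    beta = rng.normal(size=p)
    alpha = rng.normal(scale=3, size=S)
    y = X @ beta + alpha[strata] + rng.normal(size=len(strata))
    return y, X, strata


def dummy_ols(y, X, strata):
    """Oracle: explicit per-stratum intercepts, ordinary least squares."""
    D = pd.get_dummies(pd.Series(strata), dtype=float).to_numpy()
    full = np.column_stack([X, D])
    res = sm.OLS(y, full).fit()
    p = X.shape[1]
    return res.params[:p], res.bse[:p]


class TestAbsorbStrata:
    def test_single_stratum_demeaning(self):
        y_dm, X_dm, sizes, zero = absorb_strata(
            np.array([1.0, 2.0, 3.0]), np.ones((3, 1)), np.zeros(3, dtype=int)
        )
        assert np.allclose(y_dm, [-1.0, 0.0, 1.0])
        assert list(sizes) == [3]
        assert zero[0]  # a constant column is collinear with the intercepts

    def test_constant_within_strata_flagged(self):
        strata = np.array([0, 0, 1, 1])
        X = np.column_stack([[1.0, 1.0, 5.0, 5.0], [0.0, 1.0, 0.0, 2.0]])
        _, X_dm, _, zero = absorb_strata(np.zeros(4), X, strata)
        assert list(zero) == [True, False]
        assert np.allclose(X_dm[:, 0], 0.0)

    def test_single_observation_strata_zeroed(self):
        y_dm, X_dm, sizes, _ = absorb_strata(
            np.array([4.0, 1.0, 3.0]), np.arange(3.0).reshape(-1, 1),
            np.array([0, 1, 1]),
        )
        assert y_dm[0] == 0.0 and X_dm[0, 0] == 0.0


class TestFrischWaughLovell:
    def test_matches_dummy_intercept_ols_on_random_instances(self):
        """Absorb-then-fit equals explicit dummy-intercept OLS, coefficients
        and model-based SEs, across many random small instances."""
        rng = np.random.default_rng(2024)
        for _ in range(60):
            y, X, strata = _random_instance(rng)
            fit = fit_gaussian(y, X, strata)
            b_ref, se_ref = dummy_ols(y, X, strata)
            assert np.allclose(fit.params, b_ref, rtol=1e-8, atol=1e-10)
            assert np.allclose(fit.bse, se_ref, rtol=1e-8, atol=1e-10)

    def test_exact_recovery_without_noise(self):
        rng = np.random.default_rng(0)
        strata = np.repeat(np.arange(3), 10)
        X = rng.normal(size=(30, 4))
        beta = np.array([2.0, -1.0, 0.0, 0.5])
        y = X @ beta + np.array([5.0, -2.0, 1.0])[strata]
        fit = fit_gaussian(y, X, strata)
        assert np.allclose(fit.params, beta, atol=1e-10)
        assert fit.resid_var == pytest.approx(0.0, abs=1e-18)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        y, X, strata = _random_instance(rng)
        perm = rng.permutation(len(y))
        a = fit_gaussian(y, X, strata)
        b = fit_gaussian(y[perm], X[perm], strata[perm])
        assert np.allclose(a.params, b.params, atol=1e-10)

    def test_strata_shift_invariance(self):
        rng = np.random.default_rng(3)
        y, X, strata = _random_instance(rng)
        shifts = rng.normal(scale=10, size=strata.max() + 1)
        a = fit_gaussian(y, X, strata)
        b = fit_gaussian(y + shifts[strata], X, strata)
        assert np.allclose(a.params, b.params, atol=1e-9)
        assert np.allclose(a.cov, b.cov, atol=1e-9)

    def test_cluster_robust_covariance_psd(self):
        rng = np.random.default_rng(4)
        y, X, strata = _random_instance(rng)
        est = oc.StrataAbsorbedOLS(cluster_robust=True)
        est.fit(X, y, strata, cluster=strata % 2)
        w = np.linalg.eigvalsh(est.cov_)
        assert w.min() > -1e-12


class TestBuildDesign:
    def test_column_arithmetic(self, small_cohort):
        nights, _ = small_cohort
        y, X, strata, terms, names, info = build_design(
            nights, FixedEffectsSpec(seasonal_df=8)
        )
        assert X.shape[1] == 14  # 8 seasonal + 6 day-of-week
        y2, X2, *_ = build_design(
            nights, FixedEffectsSpec(seasonal_df=8, confounders=[("temp_c", 4)])
        )
        assert X2.shape[1] == 18

    def test_missing_exposure_nights_dropped(self, small_cohort):
        nights, _ = small_cohort
        nights = nights.copy()
        nights.loc[nights.index[:25], "temp_c"] = np.nan
        *_, info = build_design(
            nights, FixedEffectsSpec(confounders=[("temp_c", 4)])
        )
        assert info["n_dropped_rows"] == 25

    def test_empty_design_errors(self, small_cohort):
        nights, _ = small_cohort
        nights = nights.copy()
        nights["temp_c"] = np.nan
        with pytest.raises(ValueError, match="empty design"):
            build_design(nights, FixedEffectsSpec(confounders=[("temp_c", 4)]))

    def test_participant_year_constant_dropped_not_fatal(self, small_cohort):
        """A participant-year-level covariate is absorbed by the strata and its
        spline columns are dropped, never silently kept."""
        nights, _ = small_cohort
        m = oc.FixedEffectsSplineModel(
            confounders=[("tst_irregularity", 4)]
        ).fit(nights)
        assert all(name.startswith("tst_irregularity")
                   for name in m.result_.dropped)
        assert len(m.result_.dropped) == 4


class TestTemperatureSlopeRecovery:
    def test_linear_effect_recovered(self):
        """Simulated linear temperature effect is recovered by the adjusted
        within-strata fit to Monte-Carlo precision."""
        cfg = oc.SimConfig(n_participants=150, years=(2021,), seed=31,
                           seasonal_amplitude=8.0, temp_effect=0.5)
        from conftest import simulate_derived
        nights, _ = simulate_derived(cfg)
        m = oc.FixedEffectsSplineModel(confounders=[("temp_c", 1)]).fit(nights)
        cr = oc.percentile_contrast(m.result_, "temp_c", nights, 75, 25)
        truth = 0.5 * (cr.setting_hi - cr.setting_lo)
        se = (cr.ci_high - cr.estimate) / 1.96
        assert abs(cr.estimate - truth) < 3 * se
        assert se < 0.2 * truth  # the check is informative, not vacuous


class TestConditionalLogistic:
    def test_uninformative_strata_dropped(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 1))
        y = np.array([1, 1, 1, 1, 0, 1, 0, 1], dtype=float)
        strata = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        fit = fit_binary(y, X, strata)
        assert fit.n_strata == 1  # the all-event stratum carries no information

    def test_matched_pair_closed_form(self):
        """With binary exposure in 1:1 matched pairs the conditional estimate
        is log(n10/n01) over the discordant pairs."""
        # 6 pairs exposed-case discordant, 4 pairs unexposed-case discordant
        y, x, g = [], [], []
        for i in range(10):
            case_exposed = i < 6
            y += [1.0, 0.0]
            x += [1.0, 0.0] if case_exposed else [0.0, 1.0]
            g += [i, i]
        fit = fit_binary(np.array(y), np.array(x).reshape(-1, 1), np.array(g))
        assert fit.params[0] == pytest.approx(np.log(6 / 4), abs=1e-6)

    def test_simulated_log_or_recovery(self):
        rng = np.random.default_rng(8)
        S, n_per, beta = 300, 6, 0.5
        x = rng.normal(size=(S, n_per))
        alpha = rng.normal(scale=0.5, size=S)
        p = 1 / (1 + np.exp(-(alpha[:, None] + beta * x)))
        y = (rng.random((S, n_per)) < p).astype(float)
        strata = np.repeat(np.arange(S), n_per)
        fit = fit_binary(y.reshape(-1), x.reshape(-1, 1), strata)
        assert abs(fit.params[0] - beta) < 3 * fit.bse[0]

    def test_no_informative_strata_errors(self):
        with pytest.raises(ValueError, match="no informative strata"):
            fit_binary(np.ones(4), np.random.default_rng(0).normal(size=(4, 1)),
                       np.array([0, 0, 1, 1]))


class TestModelFitSerialization:
    def test_json_roundtrip_preserves_marginal_means(self, tmp_path, small_cohort):
        nights, _ = small_cohort
        m = oc.FixedEffectsSplineModel().fit(nights)
        path = tmp_path / "fit.json"
        m.result_.to_json(path)
        back = oc.ModelFit.from_json(path)
        grid = np.arange(1, 366)
        a = oc.emm_curve(m.result_, "day_of_year", grid, 172.0)
        b = oc.emm_curve(back, "day_of_year", grid, 172.0)
        pd.testing.assert_frame_equal(a, b)

    def test_estimator_params_interface(self):
        m = oc.FixedEffectsSplineModel(seasonal_df=4)
        assert m.get_params()["seasonal_df"] == 4
        m.set_params(seasonal_df=6)
        assert m.spec().seasonal_df == 6
        with pytest.raises(ValueError):
            m.set_params(bogus=1)
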