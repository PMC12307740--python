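import numpy as np
import pandas as pd
import pytest

import osaclim as oc
from osaclim.effects import emm_curve, odds_change, peak_trough, percentile_contrast
from osaclim.model import ModelFit, TermInfo
from osaclim.splines import natural_spline_basis


def synthetic_fit(func, df=6, x_lo=0.0, x_hi=10.0, sigma=0.0, n=400,
                  term="x", family="gaussian", seed=0):
    """A ModelFit whose single spline term was least-squares fitted to func(x).

    Gives full control over the fitted function and covariance so marginal-
    mean code can be checked against direct evaluation.
    """
    rng = np.random.default_rng(seed)
    x = np.linspace(x_lo, x_hi, n)
    X, basis = natural_spline_basis(x, df, boundary=(x_lo, x_hi), variable=term)
    Xc = X - X.mean(axis=0)  # mimic strata absorption: intercept removed
    y = func(x) + rng.normal(0, sigma, n)
    yc = y - y.mean()
    XtX_inv = np.linalg.inv(Xc.T @ Xc)
    beta = XtX_inv @ Xc.T @ yc
    resid = yc - Xc @ beta
    s2 = resid @ resid / max(n - df - 1, 1)
    cov = np.maximum(s2, 1e-12) * XtX_inv
    terms = [TermInfo(term, "spline", list(range(df)), basis)]
    return ModelFit(params=beta, cov=cov, column_names=[f"{term}{i}" for i in range(df)],
                    terms=terms, family=family, n_obs=n, n_strata=1,
                    df_resid=n - df - 1, resid_var=float(s2))


class TestEmmCurve:
    def test_reference_identity(self):
        fit = synthetic_fit(np.sin, sigma=0.1)
        c = emm_curve(fit, "x", [5.0], 5.0)
        assert c["estimate"].iloc[0] == 0.0
        assert c["ci_low"].iloc[0] <= 0.0 <= c["ci_high"].iloc[0]

    def test_linear_term_gives_line(self):
        fit = synthetic_fit(lambda x: 2.5 * x)
        grid = np.linspace(1, 9, 17)
        c = emm_curve(fit, "x", grid, 4.0)
        assert np.allclose(c["estimate"], 2.5 * (grid - 4.0), atol=1e-8)

    def test_ci_scales_with_covariance(self):
        fit = synthetic_fit(np.sin, sigma=0.3)
        doubled = ModelFit.from_dict(fit.to_dict())
        doubled.cov = 2.0 * doubled.cov
        a = emm_curve(fit, "x", [2.0, 7.0], 5.0)
        b = emm_curve(doubled, "x", [2.0, 7.0], 5.0)
        assert np.allclose(b["se"], np.sqrt(2) * a["se"])

    def test_extrapolation_flagged(self):
        fit = synthetic_fit(np.sin)
        c = emm_curve(fit, "x", [-1.0, 5.0, 11.0], 5.0)
        assert list(c["extrapolated"]) == [True, False, True]

    def test_unknown_term_errors(self):
        fit = synthetic_fit(np.sin)
        with pytest.raises(KeyError):
            emm_curve(fit, "nope", [1.0], 0.0)


class TestPercentileContrast:
    def test_equal_percentiles_zero(self):
        fit = synthetic_fit(np.sin, sigma=0.1)
        data = pd.DataFrame({"x": np.linspace(0, 10, 100)})
        cr = percentile_contrast(fit, "x", data, 50, 50)
        assert cr.estimate == 0.0

    def test_linear_slope_times_iqr(self):
        fit = synthetic_fit(lambda x: 3.0 * x)
        data = pd.DataFrame({"x": np.linspace(0, 10, 101)})
        cr = percentile_contrast(fit, "x", data, 75, 25)
        assert cr.estimate == pytest.approx(3.0 * (cr.setting_hi - cr.setting_lo),
                                            abs=1e-8)
        assert cr.ci_low <= cr.estimate <= cr.ci_high

    def test_curved_fit_matches_direct_prediction_difference(self):
        """Contrast equals independent evaluation of the fitted function at the
        two percentile settings (quadratic toy)."""
        fit = synthetic_fit(lambda x: x**2, df=8)
        data = pd.DataFrame({"x": np.linspace(0, 10, 101)})
        cr = percentile_contrast(fit, "x", data, 95, 50)
        basis = fit.term("x").basis
        direct = (basis.design([cr.setting_hi]) - basis.design([cr.setting_lo]))[0] @ fit.params
        assert cr.estimate == pytest.approx(float(direct), abs=1e-10)

    def test_delta_method_agrees_with_parametric_simulation(self):
        """On a linear contrast the two CI constructions agree closely."""
        fit = synthetic_fit(lambda x: 2.0 * x, sigma=1.0, seed=3)
        data = pd.DataFrame({"x": np.linspace(0, 10, 101)})
        cr = percentile_contrast(fit, "x", data, 75, 25)
        half_dm = (cr.ci_high - cr.ci_low) / 2
        rng = np.random.default_rng(0)
        draws = rng.multivariate_normal(fit.params, fit.cov, size=40000)
        v = (fit.term("x").basis.design([cr.setting_hi])
             - fit.term("x").basis.design([cr.setting_lo]))[0]
        sim = draws @ v
        half_sim = (np.percentile(sim, 97.5) - np.percentile(sim, 2.5)) / 2
        assert abs(half_dm - half_sim) / half_dm < 0.10


class TestPeakTrough:
    def test_flat_curve_degenerate(self):
        fit = synthetic_fit(lambda x: np.zeros_like(x))
        fit.params[:] = 0.0
        fit.cov[:] = 0.0
        sc = peak_trough(fit, "x", reference=5.0, grid=np.linspace(0, 10, 50))
        assert sc.delta == 0.0 and sc.degenerate
        assert sc.delta_ci == (0.0, 0.0)

    def test_noiseless_sinusoid_delta_is_twice_amplitude(self):
        a = 7.0
        fit = synthetic_fit(lambda x: a * np.sin(2 * np.pi * x / 10.0), df=10)
        sc = peak_trough(fit, "x", reference=5.0, grid=np.linspace(0, 10, 365),
                         n_draws=100, seed=0)
        assert sc.delta == pytest.approx(2 * a, rel=0.02)
        assert sc.delta >= 0.0

    def test_reference_invariance(self):
        """Peak-trough delta and percentile contrasts do not depend on the
        spline reference setting."""
        fit = synthetic_fit(np.cos, sigma=0.2, seed=1)
        a = peak_trough(fit, "x", reference=2.0, grid=np.linspace(0, 10, 100),
                        n_draws=500, seed=4)
        b = peak_trough(fit, "x", reference=9.0, grid=np.linspace(0, 10, 100),
                        n_draws=500, seed=4)
        assert a.delta == pytest.approx(b.delta, abs=1e-10)
        assert a.delta_ci == pytest.approx(b.delta_ci, abs=1e-10)

    def test_ties_take_earliest_day(self):
        fit = synthetic_fit(lambda x: np.zeros_like(x))
        fit.params[:] = 0.0
        sc = peak_trough(fit, "x", reference=0.0, grid=np.linspace(0, 10, 11))
        assert sc.peak_day == 0 and sc.trough_day == 0


class TestOddsChange:
    def test_zero_contrast(self):
        fit = synthetic_fit(lambda x: np.zeros_like(x), family="binomial")
        fit.params[:] = 0.0
        oc_ = odds_change(fit, "x", 5.0, 5.0)
        assert oc_.estimate == 0.0 and oc_.odds_ratio == 1.0

    def test_exact_transform(self):
        """A log-odds contrast of ln(1.2) is a +20.0% change in odds."""
        fit = synthetic_fit(lambda x: np.log(1.2) / 10.0 * x, family="binomial")
        oc_ = odds_change(fit, "x", 10.0, 0.0)
        assert oc_.estimate == pytest.approx(20.0, abs=1e-6)

    def test_requires_binomial(self):
        fit = synthetic_fit(np.sin)
        with pytest.raises(ValueError):
            odds_change(fit, "x", 1.0, 0.0)


def test_seasonal_odds_modulation_recovered():
    """A seasonal modulation of crossing the moderate-OSA threshold shows up
    in the conditional-logistic seasonal fit with the right sign and size."""
    cfg = oc.SimConfig(n_participants=100, years=(2021,), seed=41,
                       seasonal_amplitude=10.0, night_cv=0.5)
    from conftest import simulate_derived
    nights, _ = simulate_derived(cfg)
    # thin long participant-years: conditional-likelihood cost grows fast
    # with stratum length, and 25 nights per stratum carry ample signal here
    m = oc.FixedEffectsSplineModel(outcome="binary", binary_threshold=15,
                                   seasonal_df=4, max_per_stratum=25,
                                   random_state=0).fit(nights)
    sc = peak_trough(m.result_, reference=172.0, n_draws=1000, seed=1)
    res = odds_change(m.result_, "day_of_year", float(sc.peak_day),
                      float(sc.trough_day))
    assert res.estimate > 0  # odds higher at seasonal peak
    assert res.ci_low < res.estimate < res.ci_high
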