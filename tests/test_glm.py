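"""Design construction and quasi-Poisson fitting."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import heatmort as hm
from heatmort.exceptions import ConfigError, RankDeficiencyError
from heatmort.glm import Z95, build_design, fit_quasipoisson, lag_transform

from conftest import make_exposure


class TestLagTransform:
    def test_lag0_is_identity(self):
        exp = make_exposure([10.0, 20.0, 30.0])
        assert (lag_transform(exp, "lag0") == [10, 20, 30]).all()

    def test_single_lags_shift_history(self):
        exp = make_exposure([10.0, 20.0, 30.0, 40.0])
        l1 = lag_transform(exp, "lag1")
        assert np.isnan(l1.iloc[0]) and list(l1.iloc[1:]) == [10, 20, 30]
        l2 = lag_transform(exp, "lag2")
        assert l2.isna().iloc[:2].all() and list(l2.iloc[2:]) == [10, 20]

    def test_ma02_is_mean_of_three_days(self):
        exp = make_exposure([10.0, 20.0, 30.0, 40.0])
        ma = lag_transform(exp, "ma02")
        assert ma.isna().iloc[:2].all()
        assert ma.iloc[2] == pytest.approx(20.0)
        assert ma.iloc[3] == pytest.approx(30.0)

    def test_calendar_gap_invalidates_lag_history(self):
        df = make_exposure([10.0, 20.0, 30.0, 40.0]).frame.copy()
        df = df.drop(index=1).reset_index(drop=True)  # remove Jan 2
        exp = hm.ExposureSeries(df)
        l1 = lag_transform(exp, "lag1")
        # Jan 3's lag-1 day (Jan 2) is missing
        assert np.isnan(l1.loc[pd.Timestamp("2000-01-03")])
        assert l1.loc[pd.Timestamp("2000-01-04")] == 30.0


class TestBuildDesign:
    def test_heat_column_zero_below_threshold(self):
        exp = make_exposure(np.linspace(10, 25, 60), start="2000-05-01")
        spec = hm.ModelSpec(threshold=30.0, use_trend=False)
        design = build_design(exp, spec)
        assert (design.X["heat"] == 0).all()

    def test_heat_is_hockey_stick_excess(self):
        exp = make_exposure([28.0, 31.5, 29.5], start="2000-06-01")
        spec = hm.ModelSpec(threshold=29.5, use_trend=False)
        X = build_design(exp, spec).X
        assert list(X["heat"]) == [0.0, 2.0, 0.0]

    def test_ma02_drops_block_start_and_averages_before_thresholding(self):
        # series starts May 1: the first two in-season days lack history
        tmax = np.array([28.0, 30.0, 32.0, 34.0, 27.0])
        exp = make_exposure(tmax, start="2000-05-01")
        spec = hm.ModelSpec(lag="ma02", threshold=29.5, use_trend=False)
        design = build_design(exp, spec)
        assert len(design.dropped) == 2
        assert design.dates[0] == pd.Timestamp("2000-05-03")
        assert design.X["heat"].iloc[0] == pytest.approx(0.5)  # mean(28,30,32)-29.5
        assert design.X["heat"].iloc[-1] == pytest.approx(1.5)  # mean(32,34,27)-29.5

    def test_monday_row_has_one_active_dow_indicator(self):
        exp = make_exposure(np.full(14, 20.0), start="2000-05-01")  # May 1 is Monday
        X = build_design(exp, hm.ModelSpec(threshold=30.0, use_trend=False)).X
        dow_cols = [c for c in X.columns if c.startswith("dow_")]
        assert X.loc[pd.Timestamp("2000-05-01"), dow_cols].sum() == 1.0
        assert X.loc[pd.Timestamp("2000-05-01"), "dow_mon"] == 1.0
        # Sunday is the reference: all indicators zero
        assert X.loc[pd.Timestamp("2000-05-07"), dow_cols].sum() == 0.0

    def test_rows_restricted_to_season_window(self, default_sim):
        _, weather, _ = default_sim
        design = build_design(weather, hm.ModelSpec(threshold=30.0))
        assert set(design.dates.month) == {5, 6, 7, 8, 9}

    def test_trend_spline_df_scales_with_years(self, default_sim):
        _, weather, _ = default_sim
        X = build_design(weather, hm.ModelSpec(threshold=30.0)).X
        trend_cols = [c for c in X.columns if c.startswith("trend_")]
        assert len(trend_cols) == 18

    def test_pollutant_flag_without_data_is_config_error(self):
        exp = make_exposure(np.full(40, 20.0), start="2000-05-01")
        with pytest.raises(ConfigError, match="pm10"):
            build_design(exp, hm.ModelSpec(threshold=30.0, use_pm10=True, use_trend=False))

    def test_missing_pollutant_rows_dropped_and_logged(self, default_sim):
        _, weather, _ = default_sim
        spec = hm.ModelSpec(threshold=30.0, use_pm10=True, use_o3=True)
        design = build_design(weather, spec)
        assert (design.dates.year >= 2001).all()
        assert (design.dropped["date"].dt.year < 2001).all()
        assert design.dropped["reason"].str.contains("pm10").all()


class TestFit:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(4)
        y = rng.poisson(12.0, 200)
        X = pd.DataFrame({"const": np.ones(len(y))})
        fit = fit_quasipoisson(X, y)
        assert fit.params["const"] == pytest.approx(np.log(y.mean()), abs=1e-9)
        mu = y.mean()
        pearson = np.sum((y - mu) ** 2 / mu) / (len(y) - 1)
        assert fit.dispersion == pytest.approx(pearson, rel=1e-8)

    def test_dispersion_rescales_se_not_point_estimates(self, fast_sim):
        _, weather, deaths = fast_sim
        thr = hm.compute_threshold(weather, hm.ThresholdSpec(percentile=90))
        fit, design = hm.fit_cause(weather, deaths, "All cause", hm.ModelSpec(threshold=thr))
        y = deaths.align_to(design.dates)["All cause"].to_numpy()
        plain = sm.GLM(
            y.astype(float), design.X.to_numpy(), family=sm.families.Poisson()
        ).fit()
        heat_ix = list(design.X.columns).index("heat")
        assert fit.beta == pytest.approx(float(plain.params[heat_ix]), abs=1e-8)
        assert fit.se_beta == pytest.approx(
            float(plain.bse[heat_ix]) * np.sqrt(fit.dispersion), rel=1e-6
        )

    def test_ci_bounds_bracket_rr(self, fast_sim):
        _, weather, deaths = fast_sim
        thr = hm.compute_threshold(weather, hm.ThresholdSpec(percentile=90))
        fit, _ = hm.fit_cause(weather, deaths, "All cause", hm.ModelSpec(threshold=thr))
        assert fit.rr_ci_low <= fit.rr <= fit.rr_ci_high
        assert fit.dispersion > 0
        assert fit.converged

    def test_duplicate_column_rejected_by_name(self):
        X = pd.DataFrame({"const": np.ones(30), "a": np.arange(30.0)})
        X["b"] = X["a"] * 2.0
        with pytest.raises(RankDeficiencyError, match="[ab]"):
            fit_quasipoisson(X, np.ones(30))

    def test_all_zero_column_rejected(self):
        X = pd.DataFrame({"const": np.ones(30), "z": np.zeros(30)})
        with pytest.raises(RankDeficiencyError, match="z"):
            fit_quasipoisson(X, np.ones(30))

    def test_length_mismatch_rejected(self):
        X = pd.DataFrame({"const": np.ones(5)})
        with pytest.raises(ConfigError):
            fit_quasipoisson(X, np.ones(4))


class TestRelativeRisk:
    def test_null_beta_gives_unit_rr_with_log_symmetric_ci(self):
        fit = hm.FitResult(
            cause="x", beta=0.0, se_beta=0.1, dispersion=1.0, rr=1.0,
            rr_ci_low=np.exp(-Z95 * 0.1), rr_ci_high=np.exp(Z95 * 0.1),
            n_days=10, converged=True,
        )
        rr, (lo, hi) = hm.relative_risk(fit, delta=1.0)
        assert rr == 1.0
        assert np.log(hi) == pytest.approx(-np.log(lo))

    def test_forward_exponentiation(self):
        fit = hm.FitResult(
            cause="x", beta=np.log(1.07), se_beta=0.01, dispersion=1.0,
            rr=1.07, rr_ci_low=1.0, rr_ci_high=1.1, n_days=10, converged=True,
        )
        rr, _ = hm.relative_risk(fit, delta=1.0)
        assert rr == pytest.approx(1.07)

    def test_two_degree_delta_squares_rr(self):
        fit = hm.FitResult(
            cause="x", beta=np.log(1.03), se_beta=0.01, dispersion=1.0,
            rr=1.03, rr_ci_low=1.0, rr_ci_high=1.06, n_days=10, converged=True,
        )
        rr, _ = hm.relative_risk(fit, delta=2.0)
        assert rr == pytest.approx(1.0609)
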