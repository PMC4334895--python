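"""Synthetic weather/mortality generator: moments, determinism, truth recovery."""

import numpy as np
import pandas as pd
import pytest

import heatmort as hm
from heatmort.exceptions import ConfigError
from heatmort.synthetic import marginal_tmax_quantile


def single_cause_config(**kw):
    kw.setdefault("cause_baselines", {"All cause": 100.0})
    kw.setdefault("cause_parents", {})
    return hm.SyntheticConfig(**kw)


def null_effect_config(**kw):
    """All systematic effects off: homogeneous counts."""
    kw.setdefault("true_log_rr_per_degC", 0.0)
    kw.setdefault("trend_slope", 0.0)
    kw.setdefault("humidity_effect", 0.0)
    kw.setdefault("pressure_effect", 0.0)
    kw.setdefault("dow_effects", (1.0,) * 7)
    return single_cause_config(**kw)


class TestWeather:
    def test_noise_free_flat_config_gives_constant_tmax(self):
        cfg = single_cause_config(
            n_years=1, temp_mean_annual=26.5, temp_seasonal_amplitude=0.0,
            temp_daily_sd=0.0,
        )
        weather = hm.generate_weather(cfg)
        assert (weather.frame["tmax"] == 26.5).all()

    def test_seed_determinism_bit_identical(self):
        cfg = hm.SyntheticConfig(seed=42, n_years=2)
        w1, m1 = hm.simulate(cfg)
        w2, m2 = hm.simulate(cfg)
        pd.testing.assert_frame_equal(w1.frame, w2.frame)
        pd.testing.assert_frame_equal(m1.frame, m2.frame)

    def test_different_seed_differs(self):
        w1 = hm.generate_weather(hm.SyntheticConfig(seed=1, n_years=1))
        w2 = hm.generate_weather(hm.SyntheticConfig(seed=2, n_years=1))
        assert not np.allclose(w1.frame["tmax"], w2.frame["tmax"])

    def test_warm_season_mean_matches_sinusoid_expectation(self):
        cfg = hm.SyntheticConfig(seed=11)
        weather = hm.generate_weather(cfg)
        df = weather.frame
        warm = df["date"].dt.month.isin((5, 6, 7, 8, 9))
        # closed-form expectation: sinusoid averaged over the same dates;
        # the iid noise contributes SE = sd / sqrt(n)
        expected = cfg.seasonal_mean(pd.DatetimeIndex(df.loc[warm, "date"])).mean()
        n = int(warm.sum())
        se = cfg.temp_daily_sd / np.sqrt(n)
        assert abs(df.loc[warm, "tmax"].mean() - expected) < 3 * se

    def test_calendar_is_gregorian_with_leap_days(self):
        cfg = hm.SyntheticConfig(n_years=18, start_year=1992)
        dates = hm.generate_weather(cfg).dates
        assert len(dates) == 6575  # 1992-2009 includes five leap years
        assert pd.Timestamp("1996-02-29") in dates

    def test_temperature_ordering_and_covariate_bounds(self, default_sim):
        _, weather, _ = default_sim
        df = weather.frame
        assert (df["tmin"] <= df["tmean"]).all() and (df["tmean"] <= df["tmax"]).all()
        assert ((df["humidity"] > 0) & (df["humidity"] <= 100)).all()
        assert (df["pressure"] > 0).all()

    def test_pollutants_missing_before_start_year(self, default_sim):
        _, weather, _ = default_sim
        df = weather.frame
        pre = df["date"].dt.year < 2001
        assert df.loc[pre, "pm10"].isna().all()
        assert df.loc[~pre, "pm10"].notna().all()
        assert (df.loc[~pre, "pm10"] >= 0).all()


class TestMortalityMoments:
    def test_homogeneous_poisson_mean(self):
        cfg = null_effect_config(n_years=3, dispersion=1.0, seed=5)
        _, deaths = hm.simulate(cfg)
        counts = deaths.counts("All cause").to_numpy()
        se = np.sqrt(100.0 / len(counts))
        assert abs(counts.mean() - 100.0) < 3 * se

    def test_doubling_above_threshold(self):
        # flat 30.5 degC days with theta=29.5: excess exactly 1 degC
        base = dict(
            n_years=3, temp_mean_annual=30.5, temp_seasonal_amplitude=0.0,
            temp_daily_sd=0.0, true_threshold=29.5, dispersion=1.0,
            trend_slope=0.0, humidity_effect=0.0, pressure_effect=0.0,
            dow_effects=(1.0,) * 7, seed=9,
        )
        hot = single_cause_config(true_log_rr_per_degC=np.log(2.0), **base)
        ref = single_cause_config(true_log_rr_per_degC=0.0, **base)
        m_hot = hm.simulate(hot)[1].counts("All cause").mean()
        m_ref = hm.simulate(ref)[1].counts("All cause").mean()
        se_ratio = np.sqrt(2 * 200.0 / 1095) / 100.0  # delta-method on the ratio
        assert m_hot / m_ref == pytest.approx(2.0, abs=3 * np.sqrt(2) * se_ratio)

    def test_dispersion_recovered_from_var_mean_ratio(self):
        # Monte-Carlo oracle: ratio estimates across independent seeds
        ratios = []
        for seed in range(12):
            cfg = null_effect_config(
                n_years=28, dispersion=4.0, seed=100 + seed,
                cause_baselines={"x": 50.0},
            )
            counts = hm.simulate(cfg)[1].counts("x").to_numpy()[:10000]
            ratios.append(counts.var(ddof=1) / counts.mean())
        ratios = np.asarray(ratios)
        assert abs(ratios.mean() - 4.0) < 3 * ratios.std(ddof=1) / np.sqrt(len(ratios))

    def test_poisson_when_phi_one(self):
        cfg = null_effect_config(n_years=28, dispersion=1.0, seed=3)
        counts = hm.simulate(cfg)[1].counts("All cause").to_numpy()
        ratio = counts.var(ddof=1) / counts.mean()
        assert ratio == pytest.approx(1.0, abs=0.1)


class TestStructure:
    def test_subthreshold_days_unaffected_by_beta(self):
        base = dict(n_years=2, seed=21, dispersion=1.5)
        cfg_a = hm.SyntheticConfig(true_log_rr_per_degC=0.0, **base)
        cfg_b = hm.SyntheticConfig(true_log_rr_per_degC=0.5, **base)
        weather = hm.generate_weather(cfg_a)
        theta = cfg_a.resolved_threshold()
        m_a = hm.generate_mortality(weather, cfg_a).frame
        m_b = hm.generate_mortality(weather, cfg_b).frame
        below = weather.frame["tmax"].to_numpy() <= theta
        assert below.any() and (~below).any()
        for cause in cfg_a.cause_baselines:
            assert (m_a.loc[below, cause] == m_b.loc[below, cause]).all()
        assert (m_a.loc[~below] != m_b.loc[~below]).any().any()

    def test_children_never_exceed_parents(self, default_sim):
        config, _, deaths = default_sim
        df = deaths.frame
        for child, parent in config.cause_parents.items():
            assert (df[child] <= df[parent]).all(), (child, parent)

    def test_rare_cause_daily_mean_below_point_one(self, default_sim):
        _, _, deaths = default_sim
        assert deaths.counts("Schizophrenia").mean() < 0.1

    def test_default_threshold_is_marginal_q90(self):
        cfg = hm.SyntheticConfig()
        theta = cfg.resolved_threshold()
        assert theta == pytest.approx(marginal_tmax_quantile(cfg, 0.90), abs=1e-9)
        # empirical check on one long realisation
        w = hm.generate_weather(hm.SyntheticConfig(seed=8))
        frac = (w.frame["tmax"] > theta).mean()
        assert frac == pytest.approx(0.10, abs=0.01)

    @pytest.mark.parametrize(
        "field,kw",
        [
            ("n_years", {"n_years": 0}),
            ("dispersion", {"dispersion": 0.5}),
            ("cause_baselines", {"cause_baselines": {"x": -1.0}, "cause_parents": {}}),
            ("dow_effects", {"dow_effects": (1.0,) * 6}),
            ("temp_daily_sd", {"temp_daily_sd": -1.0}),
        ],
    )
    def test_invalid_config_names_field(self, field, kw):
        with pytest.raises(ConfigError, match=field):
            hm.SyntheticConfig(**kw)
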