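"""Synthetic cohort generator: climate moments, planted effects, determinism."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from heatfeed.climate import build_lag_matrix, compute_threshold, detect_heatwaves
from heatfeed.synthetic import (
    GeneratorConfig,
    default_planted_curve,
    generate_climate,
    generate_records_mode_a,
    generate_records_mode_b,
    write_climate_csv,
    write_records_csv,
)
from heatfeed.synthetic import _linear_predictor_covariates


def exposure_matrix(cfg, climate, records, max_lag=14):
    d = cfg.heatwave_definition
    cals = {cid: detect_heatwaves(s, d, compute_threshold(s, d.percentile))
            for cid, s in climate.items()}
    return build_lag_matrix(records, cals, max_lag=max_lag).to_numpy(float)


def lag0_config(**kw):
    curve = np.zeros(15)
    curve[0] = kw.pop("lag0_logor")
    return GeneratorConfig(planted_lag_curve=curve, **kw)


def empirical_log_or(y, x):
    a = np.sum(y & x) + 0.5
    b = np.sum(~y & x) + 0.5
    c = np.sum(y & ~x) + 0.5
    d = np.sum(~y & ~x) + 0.5
    return np.log(a * d / (b * c))


class TestClimateGenerator:
    def test_degenerate_constant_series(self):
        cfg = GeneratorConfig(
            seed=1, n_countries=1, clusters_per_country=1, children_per_cluster=1,
            mean_temp_range=(25.0, 25.0), seasonal_amplitude=0.0,
            noise_sd=0.0, warming_trend=0.0,
        )
        s = next(iter(generate_climate(cfg).values()))
        np.testing.assert_allclose(s.tmean, 25.0)

    def test_white_noise_sd_matches_closed_form(self):
        cfg = GeneratorConfig(
            seed=2, n_countries=1, clusters_per_country=1, children_per_cluster=1,
            date_range=("1800-01-01", "2073-10-15"),  # 100,000 days
            mean_temp_range=(25.0, 25.0), seasonal_amplitude=0.0,
            ar1_coefficient=0.0, noise_sd=1.0, warming_trend=0.0,
        )
        s = next(iter(generate_climate(cfg).values()))
        assert len(s) == 100_000
        assert np.std(s.tmean - 25.0) == pytest.approx(1.0, rel=0.02)

    def test_ar1_stationary_sd_matches_closed_form(self):
        phi, sd = 0.7, 1.5
        cfg = GeneratorConfig(
            seed=3, n_countries=1, clusters_per_country=1, children_per_cluster=1,
            date_range=("1900-01-01", "2036-12-31"),
            mean_temp_range=(25.0, 25.0), seasonal_amplitude=0.0,
            ar1_coefficient=phi, noise_sd=sd, warming_trend=0.0,
        )
        s = next(iter(generate_climate(cfg).values()))
        assert np.std(s.tmean - 25.0) == pytest.approx(sd / np.sqrt(1 - phi**2),
                                                       rel=0.02)

    def test_same_seed_is_bit_identical(self):
        cfg = GeneratorConfig(seed=7, n_countries=2, clusters_per_country=2,
                              children_per_cluster=10)
        c1, c2 = generate_climate(cfg), generate_climate(cfg)
        for cid in c1:
            np.testing.assert_array_equal(c1[cid].tmean, c2[cid].tmean)
        buf1, buf2 = io.StringIO(), io.StringIO()
        write_climate_csv(c1, buf1)
        write_climate_csv(c2, buf2)
        assert buf1.getvalue() == buf2.getvalue()

    def test_nonpositive_date_range_rejected(self):
        with pytest.raises(ValueError, match="date_range"):
            GeneratorConfig(date_range=("2005-01-01", "2004-01-01"))


class TestConfigValidation:
    def test_ar1_outside_unit_interval(self):
        with pytest.raises(ValueError, match="ar1"):
            GeneratorConfig(ar1_coefficient=1.0)

    def test_wrong_curve_length(self):
        with pytest.raises(ValueError, match="length 15"):
            GeneratorConfig(planted_lag_curve=np.zeros(10))

    def test_curve_sum_must_match_declared_cumulative(self):
        with pytest.raises(ValueError, match="sum"):
            GeneratorConfig(planted_lag_curve=np.ones(15),
                            planted_cumulative_logor=1.0)

    def test_default_curve_sums_to_headline_cumulative(self):
        curve = default_planted_curve()
        assert curve.sum() == pytest.approx(np.log(6.19), abs=1e-12)
        assert curve[0] == max(curve)  # effects are immediate and decay


class TestModeA:
    def test_null_model_prevalence_near_half(self):
        cfg = GeneratorConfig(
            seed=5, mode="A", n_countries=4, clusters_per_country=4,
            children_per_cluster=400, baseline_logit=0.0,
            covariate_effects={}, country_intercept_sd=0.0,
            planted_lag_curve=np.zeros(15),
            interview_range=("2010-01-01", "2011-12-31"),
        )
        cohort = generate_records_mode_a(cfg, generate_climate(cfg))
        prev = cohort.records["not_meeting"].mean()
        se = 0.5 / np.sqrt(len(cohort.records))
        assert abs(prev - 0.5) < 3 * se

    def test_lag0_planted_or_recovered_by_contingency_table(self):
        cfg = lag0_config(
            lag0_logor=float(np.log(6.19)), seed=6, mode="A",
            n_countries=6, clusters_per_country=8, children_per_cluster=1100,
            baseline_logit=0.0, covariate_effects={}, country_intercept_sd=0.0,
            interview_range=("2010-01-01", "2011-12-31"),
        )
        climate = generate_climate(cfg)
        cohort = generate_records_mode_a(cfg, climate)
        assert len(cohort.records) >= 50_000
        h = exposure_matrix(cfg, climate, cohort.records)
        y = cohort.records["not_meeting"].to_numpy(bool)
        got = empirical_log_or(y, h[:, 0] > 0)
        assert got == pytest.approx(np.log(6.19), abs=0.2)

    def test_no_country_heterogeneity_when_sd_zero(self):
        cfg = GeneratorConfig(
            seed=8, mode="A", n_countries=5, clusters_per_country=3,
            children_per_cluster=600, baseline_logit=0.5,
            covariate_effects={}, country_intercept_sd=0.0,
            planted_lag_curve=np.zeros(15),
            interview_range=("2010-01-01", "2011-12-31"),
        )
        cohort = generate_records_mode_a(cfg, generate_climate(cfg))
        prev = cohort.records.groupby("country_id")["not_meeting"].mean()
        n = cfg.clusters_per_country * cfg.children_per_cluster
        se = np.sqrt(0.62 * 0.38 / n)
        assert prev.max() - prev.min() < 6 * se

    def test_prevalence_matches_linear_predictor(self):
        cfg = GeneratorConfig(
            seed=9, mode="A", n_countries=4, clusters_per_country=4,
            children_per_cluster=500,
            interview_range=("2010-01-01", "2011-12-31"),
        )
        climate = generate_climate(cfg)
        cohort = generate_records_mode_a(cfg, climate)
        rec = cohort.records
        h = exposure_matrix(cfg, climate, rec)
        lp = (cfg.baseline_logit
              + _linear_predictor_covariates(rec, cfg.covariate_effects)
              + cohort.country_intercepts[rec["country_id"]].to_numpy()
              + h @ cfg.planted_lag_curve)
        p = expit(lp)
        mc_se = np.sqrt(np.sum(p * (1 - p))) / len(rec)
        assert abs(rec["not_meeting"].mean() - p.mean()) < 3 * mc_se

    def test_records_have_full_climate_history(self):
        cfg = GeneratorConfig(seed=10, n_countries=2, clusters_per_country=2,
                              children_per_cluster=50)
        climate = generate_climate(cfg)
        cohort = generate_records_mode_a(cfg, climate)
        for cid, date in zip(cohort.records["cluster_id"],
                             cohort.records["interview_date"]):
            s = climate[cid]
            assert s.day_index(date) >= 21
        ages = cohort.records["age_months"]
        assert ages.min() >= 6 and ages.max() <= 23


class TestModeB:
    def test_base_rates_recovered_without_heat_effect(self):
        cfg = GeneratorConfig(
            seed=11, mode="B", n_countries=3, clusters_per_country=4,
            children_per_cluster=800,
            heat_sensitivity={},
            interview_range=("2010-01-01", "2011-12-31"),
        )
        cohort = generate_records_mode_b(cfg, generate_climate(cfg))
        n = len(cohort.records)
        for grp, base in cfg.base_rates.items():
            se = np.sqrt(base * (1 - base) / n)
            assert abs(cohort.records[grp].mean() - base) < 3 * se, grp

    def test_vegetable_sensitivity_recovered_by_contingency_table(self):
        curve = np.zeros(15)
        curve[0] = 1.0  # lag-weight shape concentrated on the recall day
        cfg = GeneratorConfig(
            seed=12, mode="B", n_countries=6, clusters_per_country=8,
            children_per_cluster=1100,
            planted_lag_curve=curve,
            heat_sensitivity={"fg_vita_fruit_veg": float(np.log(5.82))},
            interview_range=("2010-01-01", "2011-12-31"),
        )
        climate = generate_climate(cfg)
        cohort = generate_records_mode_b(cfg, climate)
        h = exposure_matrix(cfg, climate, cohort.records)
        no_veg = ~cohort.records["fg_vita_fruit_veg"].to_numpy(bool)
        got = empirical_log_or(no_veg, h[:, 0] > 0)
        assert got == pytest.approx(np.log(5.82), abs=0.2)

    def test_indicators_not_stored(self, small_cohort):
        assert not {"mdd", "mmf", "mad"} & set(small_cohort.records.columns)

    def test_zero_breastfeeding_rate_forces_nonbreastfed_branches(self):
        from heatfeed.indicators import classify_frame

        cfg = GeneratorConfig(
            seed=13, mode="B", n_countries=2, clusters_per_country=2,
            children_per_cluster=200, breastfed_logit_intercept=-50.0,
            interview_range=("2010-01-01", "2011-12-31"),
        )
        cohort = generate_records_mode_b(cfg, generate_climate(cfg))
        rec = cohort.records
        assert not rec["is_breastfed"].any()
        assert not rec["fg_breastmilk"].any()
        ind = classify_frame(rec)
        # non-breastfed branch: MAD requires at least two milk feeds
        few_milk = rec.set_index("record_id")["milk_feed_count"] < 2
        assert not ind.loc[few_milk, "mad"].any()

    def test_mode_b_determinism(self):
        cfg = GeneratorConfig(seed=14, mode="B", n_countries=2,
                              clusters_per_country=2, children_per_cluster=50)
        climate = generate_climate(cfg)
        r1 = generate_records_mode_b(cfg, climate).records
        r2 = generate_records_mode_b(cfg, climate).records
        b1, b2 = io.StringIO(), io.StringIO()
        write_records_csv(r1, b1)
        write_records_csv(r2, b2)
        assert b1.getvalue() == b2.getvalue()


def test_mode_mismatch_rejected():
    cfg = GeneratorConfig(seed=1, mode="A", n_countries=1,
                          clusters_per_country=1, children_per_cluster=10)
    climate = generate_climate(cfg)
    with pytest.raises(ValueError, match="mode"):
        generate_records_mode_b(cfg, climate)
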