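import numpy as np
import pandas as pd
import pytest

from stormlag.community import COVARIATES
from stormlag.matching import LAGS
from stormlag.synthetic import (
    SUBGROUP_SHARES,
    SUBGROUPS,
    ScenarioConfig,
    generate_community,
    generate_counts,
    generate_denominators,
    generate_storm_calendar,
    simulate_dataset,
)


class TestScenarioValidation:
    def test_defaults_are_valid(self):
        ScenarioConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"year_end": 1990},
            {"storms_per_year": -0.1},
            {"true_lag_betas": (0.0,) * 9},
            {"dow_effects": (0.1,) + (0.0,) * 6},  # reference not zero
            {"year_effects": (0.1, 0.0)},  # first year not reference
            {"random_intercept_sd": -1.0},
            {"denominator_range": (0, 10)},
            {"season": (11, 6)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        base = dict(year_start=2000, year_end=2001)
        base.update(kwargs)
        with pytest.raises(ValueError):
            ScenarioConfig(**base)


class TestStormCalendar:
    def test_zero_rate_gives_empty_calendar(self):
        cfg = ScenarioConfig(n_zctas=5, storms_per_year=0.0, seed=1)
        assert len(generate_storm_calendar(cfg)) == 0

    def test_fixed_seed_reproducible(self):
        cfg = ScenarioConfig(n_zctas=20, seed=9)
        a, b = generate_storm_calendar(cfg), generate_storm_calendar(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_mean_storm_burden_matches_calibration(self):
        # 0.226 storms per ZCTA-year over 18 years ~ 4.07 storms per ZCTA,
        # the observed mean burden the defaults are calibrated to.
        cfg = ScenarioConfig(n_zctas=200, storms_per_year=0.226, seed=4)
        events = generate_storm_calendar(cfg)
        per_zcta = events.groupby("zcta_id").size()
        mean = per_zcta.sum() / cfg.n_zctas  # zero-storm ZCTAs count too
        assert mean == pytest.approx(4.07, abs=3 * np.sqrt(4.07 / 200))

    def test_all_windspeeds_qualify(self):
        events = generate_storm_calendar(ScenarioConfig(n_zctas=50, seed=2))
        assert (events["windspeed"] >= 21.0).all()

    def test_dates_within_season(self):
        cfg = ScenarioConfig(n_zctas=50, seed=3)
        events = generate_storm_calendar(cfg)
        months = pd.to_datetime(events["closest_date"]).dt.month
        assert months.between(6, 11).all()


class TestCommunityGeneration:
    def test_identity_correlation_near_zero(self):
        cfg = ScenarioConfig(
            n_zctas=2000, community_correlation=np.eye(10), seed=5
        )
        cov = generate_community(cfg)
        latent_r = cov[COVARIATES].rank().corr()  # rank-based: transform-proof
        off = latent_r.to_numpy()[~np.eye(10, dtype=bool)]
        assert np.abs(off).max() < 0.08

    def test_strong_pairwise_correlation_recovered(self):
        R = np.eye(10)
        i, j = COVARIATES.index("income"), COVARIATES.index("housing_value")
        R[i, j] = R[j, i] = 0.9
        cfg = ScenarioConfig(n_zctas=1000, community_correlation=R, seed=6)
        cov = generate_community(cfg)
        # both marginals are lognormal in income/housing value: correlate logs
        r = np.corrcoef(np.log(cov["income"]), np.log(cov["housing_value"]))[0, 1]
        assert r == pytest.approx(0.9, abs=0.05)

    def test_non_positive_definite_rejected(self):
        R = np.eye(10)
        R[0, 1] = R[1, 0] = 0.99
        R[1, 2] = R[2, 1] = 0.99
        R[0, 2] = R[2, 0] = -0.99
        with pytest.raises(ValueError, match="positive definite"):
            generate_community(ScenarioConfig(community_correlation=R))

    def test_two_zctas_split_one_each_side(self):
        ds = simulate_dataset(ScenarioConfig(n_zctas=2, seed=7))
        for c in COVARIATES:
            labels = ds.community[f"label_{c}"]
            assert sorted(labels) == ["above", "below"]

    def test_percentage_covariates_bounded(self):
        cov = generate_community(ScenarioConfig(n_zctas=500, seed=8))
        for c in ("education", "poverty", "pct_non_english", "pct_urban",
                  "pct_black", "pct_owner_occupied"):
            assert cov[c].between(0, 100).all()


class TestCounts:
    def test_null_model_mean_rate(self):
        cfg = ScenarioConfig(
            n_zctas=30, year_start=2000, year_end=2005, storms_per_year=0.0,
            random_intercept_sd=0.0, dow_effects=(0.0,) * 7,
            baseline_log_rate=-9.0, seed=10, subgroup_resolution=False,
        )
        denoms = generate_denominators(cfg, np.random.default_rng(10))
        counts, _, _ = generate_counts(
            cfg, generate_storm_calendar(cfg), denoms,
            rng=np.random.default_rng(11),
        )
        merged = counts.assign(year=counts["date"].dt.year).merge(
            denoms, on=["zcta_id", "year"]
        )
        rate = merged["count"].sum() / merged["denominator"].sum()
        assert rate == pytest.approx(np.exp(-9.0), rel=0.02)

    def test_lag0_doubling_recovered_empirically(self):
        # beta = ln 2 at lag 0: storm days should show twice the event rate
        # of all other days (closed-form rate ratio; >=1e5 zcta-days).
        betas = [0.0] * 10
        betas[LAGS.index(0)] = np.log(2.0)
        cfg = ScenarioConfig(
            n_zctas=60, year_start=2000, year_end=2009, storms_per_year=0.4,
            true_lag_betas=tuple(betas), random_intercept_sd=0.0,
            dow_effects=(0.0,) * 7, baseline_log_rate=-8.0, seed=12,
            subgroup_resolution=False,
        )
        events = generate_storm_calendar(cfg, np.random.default_rng(12))
        denoms = generate_denominators(cfg, np.random.default_rng(13))
        counts, _, _ = generate_counts(cfg, events, denoms,
                                       rng=np.random.default_rng(14))
        assert len(counts) >= 1e5
        counts = counts.assign(year=counts["date"].dt.year).merge(
            denoms, on=["zcta_id", "year"]
        )
        storm_key = set(
            zip(events["zcta_id"], pd.to_datetime(events["closest_date"]))
        )
        on_storm = pd.Series(
            list(zip(counts["zcta_id"], counts["date"])), index=counts.index
        ).isin(storm_key)
        rate_storm = counts.loc[on_storm, "count"].sum() / counts.loc[on_storm, "denominator"].sum()
        rate_rest = counts.loc[~on_storm, "count"].sum() / counts.loc[~on_storm, "denominator"].sum()
        ratio = rate_storm / rate_rest
        n_storm_events = counts.loc[on_storm, "count"].sum()
        mc_se = 2.0 / np.sqrt(n_storm_events)  # delta-method on the ratio
        assert abs(ratio - 2.0) < 3 * mc_se + 0.02

    def test_storm_outside_period_rejected(self):
        cfg = ScenarioConfig(n_zctas=2, year_start=2000, year_end=2001, seed=1)
        events = pd.DataFrame(
            {"storm_id": ["S"], "zcta_id": ["Z0000"],
             "closest_date": [pd.Timestamp("2005-09-01")], "windspeed": [30.0]}
        )
        denoms = generate_denominators(cfg)
        with pytest.raises(ValueError, match="outside"):
            generate_counts(cfg, events, denoms)

    def test_rate_ceiling_guard(self):
        cfg = ScenarioConfig(n_zctas=2, year_start=2000, year_end=2000,
                             baseline_log_rate=5.0, rate_ceiling=1e3, seed=1)
        denoms = generate_denominators(cfg)
        with pytest.raises(ValueError, match="ceiling"):
            generate_counts(cfg, generate_storm_calendar(cfg), denoms)


class TestDatasetConsistency:
    def test_every_zcta_day_has_a_row(self, small_scenario, small_dataset):
        n_days = (
            pd.Timestamp(f"{small_scenario.year_end}-12-31")
            - pd.Timestamp(f"{small_scenario.year_start}-01-01")
        ).days + 1
        assert len(small_dataset.counts) == small_scenario.n_zctas * n_days
        assert small_dataset.counts["count"].ge(0).all()

    def test_subgroup_counts_sum_to_totals(self, small_dataset):
        assert small_dataset.subgroup_counts.shape[1] == len(SUBGROUPS)
        np.testing.assert_array_equal(
            small_dataset.subgroup_counts.sum(axis=1),
            small_dataset.counts["count"].to_numpy(),
        )

    def test_stratifier_accessors_partition_counts(self, small_dataset):
        for strat in ("age", "sex", "dual"):
            by = small_dataset.counts_by(strat)
            total = sum(df["count"].to_numpy() for df in by.values())
            np.testing.assert_array_equal(
                total, small_dataset.counts["count"].to_numpy()
            )
            denom_by = small_dataset.denominators_by(strat)
            total_denom = sum(df["denominator"].to_numpy() for df in denom_by.values())
            np.testing.assert_allclose(
                total_denom, small_dataset.denominators["denominator"].to_numpy()
            )

    def test_identical_config_identical_dataset(self, small_scenario):
        a = simulate_dataset(small_scenario)
        b = simulate_dataset(small_scenario)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.storm_events, b.storm_events)
        pd.testing.assert_frame_equal(a.community, b.community)
        np.testing.assert_array_equal(a.subgroup_counts, b.subgroup_counts)

    def test_subgroup_shares_sum_to_one(self):
        assert SUBGROUP_SHARES.sum() == pytest.approx(1.0)

    def test_roundtrip_write(self, tmp_path, small_dataset):
        small_dataset.write(tmp_path)
        for name in ("storm_events.csv", "counts.csv", "denominators.csv",
                     "community.csv", "scenario.yaml"):
            assert (tmp_path / name).exists()
        import yaml

        with open(tmp_path / "scenario.yaml") as fh:
            cfg = ScenarioConfig.from_dict(yaml.safe_load(fh))
        assert cfg == small_dataset.truth
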