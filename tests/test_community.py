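import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import pearson_matrix, welch_t
from stormlag.community import (
    COVARIATES,
    build_profiles,
    compare_strata,
    correlation_matrix,
    interpolate_boundaries,
    median_split,
    stability_check,
    time_weighted_average,
)


class TestInterpolateBoundaries:
    def test_even_split(self):
        old = pd.Series({"A": 10.0, "B": 20.0})
        overlap = pd.DataFrame(
            {"old_id": ["A", "B"], "new_id": ["N", "N"], "weight": [0.5, 0.5]}
        )
        assert interpolate_boundaries(old, overlap)["N"] == pytest.approx(15.0)

    def test_identity(self):
        old = pd.Series({"A": 42.0})
        overlap = pd.DataFrame({"old_id": ["A"], "new_id": ["N"], "weight": [1.0]})
        assert interpolate_boundaries(old, overlap)["N"] == pytest.approx(42.0)

    def test_unequal_weights_match_hand_computation(self):
        old = pd.Series({"A": 3.0, "B": 7.0, "C": 11.0})
        overlap = pd.DataFrame(
            {
                "old_id": ["A", "B", "C"],
                "new_id": ["N", "N", "N"],
                "weight": [2.0, 5.0, 1.0],
            }
        )
        expected = (3 * 2 + 7 * 5 + 11 * 1) / 8
        assert interpolate_boundaries(old, overlap)["N"] == pytest.approx(expected)

    def test_zero_total_weight_flagged_missing(self):
        old = pd.Series({"A": 1.0})
        overlap = pd.DataFrame({"old_id": ["A"], "new_id": ["N"], "weight": [0.0]})
        assert np.isnan(interpolate_boundaries(old, overlap)["N"])

    def test_negative_weight_rejected(self):
        old = pd.Series({"A": 1.0})
        overlap = pd.DataFrame({"old_id": ["A"], "new_id": ["N"], "weight": [-0.1]})
        with pytest.raises(ValueError):
            interpolate_boundaries(old, overlap)

    @settings(derandomize=True, max_examples=50)
    @given(
        values=st.lists(st.floats(-100, 100), min_size=2, max_size=6),
        raw_weights=st.lists(st.floats(0.01, 10), min_size=2, max_size=6),
    )
    def test_output_within_contributing_range(self, values, raw_weights):
        k = min(len(values), len(raw_weights))
        old = pd.Series(dict(zip([f"U{i}" for i in range(k)], values[:k])))
        overlap = pd.DataFrame(
            {"old_id": old.index, "new_id": "N", "weight": raw_weights[:k]}
        )
        out = interpolate_boundaries(old, overlap)["N"]
        assert min(values[:k]) - 1e-9 <= out <= max(values[:k]) + 1e-9


class TestTimeWeightedAverage:
    def test_two_epochs(self):
        obs = pd.DataFrame(
            {"zcta_id": ["Z", "Z"], "value": [10.0, 20.0], "weight": [5.0, 5.0]}
        )
        assert time_weighted_average(obs)["Z"] == pytest.approx(15.0)

    def test_single_observation(self):
        obs = pd.DataFrame({"zcta_id": ["Z"], "value": [7.5], "weight": [3.0]})
        assert time_weighted_average(obs)["Z"] == pytest.approx(7.5)

    def test_three_epoch_fixture(self):
        obs = pd.DataFrame(
            {"zcta_id": ["Z"] * 3, "value": [1.0, 4.0, 10.0], "weight": [2, 7, 9]}
        )
        expected = (1 * 2 + 4 * 7 + 10 * 9) / 18
        assert time_weighted_average(obs)["Z"] == pytest.approx(expected)

    def test_nonpositive_weight_rejected(self):
        obs = pd.DataFrame({"zcta_id": ["Z"], "value": [1.0], "weight": [0.0]})
        with pytest.raises(ValueError):
            time_weighted_average(obs)


class TestMedianSplit:
    def test_tie_rule_at_median(self):
        labels, med = median_split(pd.Series({"a": 1.0, "b": 2.0, "c": 3.0}))
        assert med == 2.0
        assert labels.to_dict() == {"a": "below", "b": "below", "c": "above"}

    def test_even_split_without_ties(self):
        # 796 distinct values split exactly 398 / 398
        rng = np.random.default_rng(0)
        values = pd.Series(rng.permutation(796).astype(float))
        labels, _ = median_split(values)
        assert (labels == "above").sum() == 398
        assert (labels == "below").sum() == 398

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40))
    def test_partition_against_sort_based_oracle(self, values):
        s = pd.Series(values, index=range(len(values)))
        labels, med = median_split(s)
        assert med == pytest.approx(float(np.median(values)))
        for v, lab in zip(values, labels):
            assert lab == ("above" if v > med else "below")
        n_above, n_below = (labels == "above").sum(), (labels == "below").sum()
        assert n_above + n_below == len(values)  # everyone labeled exactly once
        if len(set(values)) == len(values):  # tie-free: split is balanced
            assert abs(n_above - n_below) <= 1

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            median_split(pd.Series([np.nan, np.nan]))


class TestStabilityCheck:
    def test_identity(self):
        v = pd.Series([1.0, 5.0, 2.0, 9.0])
        res = stability_check(v, v)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.fraction_crossing_median == 0.0
        assert res.passes

    def test_anti_identity(self):
        v = pd.Series([1.0, 5.0, 2.0, 9.0])
        res = stability_check(v, -(v - v.mean()) + v.mean())
        assert res.pearson_r == pytest.approx(-1.0)
        assert not res.passes

    def test_zero_variance_flagged(self):
        res = stability_check(pd.Series([1.0, 1.0, 1.0]), pd.Series([1.0, 2.0, 3.0]))
        assert np.isnan(res.pearson_r)
        assert not res.passes

    def test_stable_covariate_rarely_crosses_median(self):
        # Highly persistent covariate: end = begin + small noise.  The
        # fraction of units flipping sides of the period median stays
        # under 8% (the level at which a fixed median split is trusted).
        rng = np.random.default_rng(12)
        begin = pd.Series(rng.normal(size=2000))
        end = begin + rng.normal(scale=0.2, size=2000)
        res = stability_check(begin, end)
        assert res.pearson_r > 0.85
        assert res.fraction_crossing_median < 0.08
        assert res.passes


class TestCompareStrata:
    def test_identical_groups(self):
        v = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = pd.Series(["above"] * 3 + ["below"] * 3)
        res = compare_strata(v, labels)
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_separated_groups(self):
        rng = np.random.default_rng(1)
        v = pd.Series(
            np.concatenate([rng.normal(0, 1e-3, 4), 1 + rng.normal(0, 1e-3, 4)])
        )
        labels = pd.Series(["below"] * 4 + ["above"] * 4)
        assert compare_strata(v, labels).p_value < 1e-6

    def test_matches_welch_formula(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(1.0, 1.0, 10), rng.normal(0.2, 2.0, 10)
        v = pd.Series(np.concatenate([a, b]))
        labels = pd.Series(["above"] * 10 + ["below"] * 10)
        res = compare_strata(v, labels)
        t_ref, p_ref = welch_t(a, b)
        assert res.t_statistic == pytest.approx(t_ref)
        assert res.p_value == pytest.approx(p_ref)

    def test_small_stratum_rejected(self):
        v = pd.Series([1.0, 2.0, 3.0])
        labels = pd.Series(["above", "below", "below"])
        with pytest.raises(ValueError):
            compare_strata(v, labels)


class TestCorrelationMatrix:
    def _profiles(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(size=(n, len(COVARIATES))), columns=COVARIATES
        )

    def test_duplicated_column_gives_unit_correlation(self):
        p = self._profiles()
        p["poverty"] = p["income"]
        m = correlation_matrix(p)
        assert m.loc["poverty", "income"] == pytest.approx(1.0)

    def test_independent_draws_near_zero(self):
        m = correlation_matrix(self._profiles(n=4000))
        off = m.to_numpy()[~np.eye(len(COVARIATES), dtype=bool)]
        assert np.abs(off).max() < 0.06

    def test_matches_brute_force_on_five_profiles(self):
        p = self._profiles(n=5, seed=9)
        m = correlation_matrix(p).to_numpy()
        ref = pearson_matrix(p.to_numpy())
        np.testing.assert_allclose(m, ref, atol=1e-12)

    def test_symmetric_psd_unit_diagonal(self):
        m = correlation_matrix(self._profiles(n=30)).to_numpy()
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m), 1.0)
        assert np.linalg.eigvalsh(m).min() > -1e-8
        assert np.abs(m).max() <= 1 + 1e-12

    def test_constant_covariate_flagged(self):
        p = self._profiles()
        p["pct_urban"] = 3.0
        m = correlation_matrix(p)
        assert m.loc["pct_urban"].drop("pct_urban").isna().all()


def test_build_profiles_labels_every_covariate():
    rng = np.random.default_rng(2)
    cov = pd.DataFrame(
        rng.normal(size=(21, len(COVARIATES))),
        columns=COVARIATES,
        index=[f"Z{i}" for i in range(21)],
    )
    profiles, medians = build_profiles(cov)
    for c in COVARIATES:
        assert set(profiles[f"label_{c}"].unique()) <= {"above", "below"}
        assert medians[c] == pytest.approx(float(cov[c].median()))
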