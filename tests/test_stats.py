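"""Group summaries, Mann-Whitney battery, KS subgroup check, regression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from flavimetry.stats import (
    group_summary,
    hypothesis_battery,
    ks_subgroup_check,
    metric_regression,
    mwu_one_sided,
    significance_stars,
)


def mwu_enumeration_oracle(x, y, alternative):
    """Exact one-sided p by exhaustive enumeration of all rank assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)
    observed_u = sum(
        1.0 if xi > yj else (0.5 if xi == yj else 0.0)
        for xi in x
        for yj in y
    )
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(
            sum(1.0 if a > b else (0.5 if a == b else 0.0) for a in xs for b in ys)
        )
    us = np.array(us)
    if alternative == "greater":
        return float(np.mean(us >= observed_u))
    return float(np.mean(us <= observed_u))


class TestGroupSummary:
    def test_five_point_example(self):
        assert group_summary([1, 2, 3, 4, 5]) == (3.0, 2.0, 4.0)

    def test_single_value_degenerate(self):
        assert group_summary([7.5]) == (7.5, 7.5, 7.5)

    def test_normal_draws_match_closed_form_quantiles(self):
        values = np.random.default_rng(1).standard_normal(10_000)
        med, q25, q75 = group_summary(values)
        assert med == pytest.approx(0.0, abs=0.03)
        assert q25 == pytest.approx(-0.6745, abs=0.03)
        assert q75 == pytest.approx(0.6745, abs=0.03)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            group_summary([])


class TestMannWhitney:
    def test_textbook_enumeration_case(self):
        # C(4,2)=6 assignments; only the observed one is as extreme
        _, p = mwu_one_sided([3, 4], [1, 2], "greater")
        assert p == pytest.approx(1 / 6)

    def test_identical_constant_groups_not_significant(self):
        _, p = mwu_one_sided([2.0, 2.0, 2.0], [2.0, 2.0, 2.0], "greater")
        assert p >= 0.5

    def test_agrees_with_enumeration_oracle_small_samples(self):
        rng = np.random.default_rng(6)
        for n1, n2 in [(2, 2), (3, 3), (2, 5), (4, 4), (3, 5)]:
            for alt in ("greater", "less"):
                for _ in range(4):
                    x = rng.normal(size=n1)
                    y = rng.normal(size=n2)
                    _, p = mwu_one_sided(x, y, alt)
                    assert p == pytest.approx(
                        mwu_enumeration_oracle(x, y, alt), abs=1e-12
                    )

    def test_calibrated_separation_detected(self, presets):
        from flavimetry.cohort import sample_group_metrics

        rng = np.random.default_rng(9)
        mng = sample_group_metrics(presets["MNG"], 64, rng)["tau_ns"]
        ctl = sample_group_metrics(presets["CTL"], 16, rng)["tau_ns"]
        _, p = mwu_one_sided(mng, ctl, "greater")
        assert p < 0.05

    def test_type_one_error_within_binomial_band(self):
        """Empirical rejection rate at alpha=0.05 over 2000 null simulations."""
        rng = np.random.default_rng(2023)
        alpha, n_sim = 0.05, 2000
        rejections = 0
        for _ in range(n_sim):
            x = rng.normal(size=16)
            y = rng.normal(size=20)
            _, p = mwu_one_sided(x, y, "greater")
            rejections += p < alpha
        rate = rejections / n_sim
        band = 3 * np.sqrt(alpha * (1 - alpha) / n_sim)
        assert rate <= alpha + band

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mwu_one_sided([], [1.0], "greater")


class TestKSSubgroupCheck:
    def test_self_comparison_p_one(self):
        v = np.random.default_rng(0).normal(size=50)
        p = ks_subgroup_check([v, v.copy()])
        assert p[0, 1] == pytest.approx(1.0)

    def test_same_shape_different_location_scale_high_p(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 500)
        b = rng.normal(5, 3, 500)
        p = ks_subgroup_check([a, b])
        assert p[0, 1] > 0.05

    def test_different_shapes_detected(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=500)
        b = rng.standard_cauchy(size=500)
        p = ks_subgroup_check([a, b])
        assert p[0, 1] < 0.05

    def test_zero_variance_subgroup_raises(self):
        with pytest.raises(ValueError):
            ks_subgroup_check([np.ones(5), np.random.default_rng(0).normal(size=5)])


class TestRegression:
    def test_collinear_decreasing_r_minus_one(self):
        x = np.linspace(0, 1, 10)
        res = metric_regression(2.0 - 3.0 * x, x)
        assert res.pearson_r == pytest.approx(-1.0)
        assert res.slope == pytest.approx(-3.0)
        assert res.intercept == pytest.approx(2.0)

    def test_independent_permuted_near_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10_000)
        y = rng.permutation(rng.normal(size=10_000))
        res = metric_regression(y, x)
        assert abs(res.pearson_r) < 0.05

    def test_small_instance_matches_covariance_formula(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=12)
        y = 0.5 * x + rng.normal(size=12)
        res = metric_regression(y, x)
        r_oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert res.pearson_r == pytest.approx(float(r_oracle), rel=1e-12)

    def test_zero_variance_rr_raises(self):
        with pytest.raises(ValueError):
            metric_regression([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])

    def test_calibrated_cohort_near_published_correlation(self, cohort_df):
        res = metric_regression(cohort_df["r_flavin"], cohort_df["redox_ratio"])
        assert res.pearson_r == pytest.approx(-0.87, abs=0.05)


class TestHypothesisBattery:
    def test_row_count_and_significance_pattern(self, cohort_df):
        battery = hypothesis_battery(cohort_df)
        # (5 groups) x (3 metrics): tumor rows carry p, CTL rows do not
        assert len(battery) == 15
        assert battery["p_value"].isna().sum() == 3
        # calibrated separation: LGG/HGG/MNG significant in all metrics
        sig = battery[battery["group"].isin(["LGG", "HGG", "MNG"])]
        assert (sig["p_value"] < 0.05).all()

    def test_missing_ctl_raises(self, cohort_df):
        no_ctl = cohort_df[cohort_df["group"] != "CTL"]
        with pytest.raises(ValueError):
            hypothesis_battery(no_ctl)

    def test_single_record_tumor_group_uses_exact_path(self, cohort_df):
        ctl = cohort_df[cohort_df["group"] == "CTL"].iloc[:8]
        one = cohort_df[cohort_df["group"] == "MNG"].iloc[:1]
        battery = hypothesis_battery(pd.concat([ctl, one]))
        row = battery[(battery["group"] == "MNG") & (battery["metric"] == "tau_ns")]
        assert row["median"].iloc[0] == row["q25"].iloc[0] == row["q75"].iloc[0]
        assert 0 < row["p_value"].iloc[0] <= 1

    def test_null_cohort_star_rate_at_alpha(self, presets):
        """When tumor groups share the CTL distribution, one-sided rejections
        at alpha occur at roughly the nominal rate."""
        from flavimetry.cohort import GROUPS, generate_cohort

        null_presets = {
            g: type(presets[g])(
                name=g,
                n_points=presets[g].n_points,
                g_center=presets["CTL"].g_center,
                g_scale=presets["CTL"].g_scale,
                marginals=presets["CTL"].marginals,
                coupling=presets["CTL"].coupling,
                anchor_495=presets["CTL"].anchor_495,
            )
            for g in GROUPS
        }
        n_tests = rejected = 0
        for seed in range(10):
            df = generate_cohort(null_presets, seed=1000 + seed).to_dataframe()
            battery = hypothesis_battery(df)
            tumor = battery[battery["group"] != "CTL"]
            n_tests += len(tumor)
            rejected += int((tumor["p_value"] < 0.05).sum())
        rate = rejected / n_tests
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_tests)

    def test_star_thresholds(self):
        assert significance_stars(0.004) == "*"
        assert significance_stars(5e-6) == "**"
        assert significance_stars(0.04) == ""
        assert significance_stars(None) == ""
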