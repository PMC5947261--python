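"""Inference layer: covariate construction, LMM/OLS fits, tests, r², Spearman."""

import datetime

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isoniche import models
from isoniche.data import GroupCensus, WeightObservation


def _census(day, n, group="G"):
    return GroupCensus(group_id=group, date=day, n_members=n)


def _obs(w1, w2):
    return WeightObservation(
        individual_id="i",
        group_id="g",
        date=datetime.date(2014, 1, 1),
        weight_first_g=w1,
        weight_second_g=w2,
        age_years=3.0,
        sex="female",
        rainfall_60d_mm=100.0,
        group_size_first_morning=10,
    )


class TestCovariates:
    @pytest.mark.parametrize("w1, w2, expected", [(1000, 995, -5), (800, 800, 0), (995, 1000, 5)])
    def test_daily_weight_change(self, w1, w2, expected):
        assert models.daily_weight_change(_obs(w1, w2)) == expected

    def test_daily_weight_change_missing_second(self):
        assert models.daily_weight_change(_obs(1000, None)) is None

    def test_mean_group_size_constant(self):
        d0 = datetime.date(2014, 1, 1)
        census = [_census(d0 + datetime.timedelta(days=3 * i), 10) for i in range(20)]
        assert models.mean_daily_group_size(census, "G", d0, d0 + datetime.timedelta(days=30)) == 10.0

    def test_mean_group_size_step_change(self):
        d0 = datetime.date(2014, 1, 1)
        census = [_census(d0 + datetime.timedelta(days=i), 10 if i < 10 else 20) for i in range(20)]
        mean = models.mean_daily_group_size(census, "G", d0, d0 + datetime.timedelta(days=19))
        assert mean == 15.0

    def test_empty_window_raises(self):
        d0 = datetime.date(2014, 1, 1)
        with pytest.raises(models.MissingDataError):
            models.mean_daily_group_size([_census(d0, 10)], "G", d0, d0 - datetime.timedelta(days=1))

    def test_no_census_coverage_raises(self):
        d0 = datetime.date(2014, 1, 1)
        with pytest.raises(models.MissingDataError):
            models.mean_daily_group_size(
                [_census(d0, 10)], "G", d0 + datetime.timedelta(days=10), d0 + datetime.timedelta(days=12)
            )

    def test_forward_fill_limited_to_three_days(self):
        d0 = datetime.date(2014, 1, 1)
        census = [_census(d0, 10), _census(d0 + datetime.timedelta(days=10), 20)]
        # days 0-3 filled at 10, 4-9 uncovered, 10-13 at 20
        mean = models.mean_daily_group_size(census, "G", d0, d0 + datetime.timedelta(days=13))
        assert mean == pytest.approx((4 * 10 + 4 * 20) / 8)

    @pytest.mark.parametrize("size, expected", [(12.3, "small"), (22.0, "large"), (17.0, "large")])
    def test_classify_group_size(self, size, expected):
        assert models.classify_group_size(size) == expected

    def test_proportion_sampled(self):
        roster = [f"i{k}" for k in range(10)]
        assert models.proportion_sampled(roster, roster[:4]) == pytest.approx(0.4)
        assert models.proportion_sampled(roster, roster) == 1.0
        assert models.proportion_sampled(roster, []) == 0.0
        with pytest.raises(ValueError):
            models.proportion_sampled([], [])
        with pytest.raises(ValueError):
            models.proportion_sampled(roster[:2], ["stranger"])


class TestLikelihoodRatioTest:
    def test_identical_likelihoods(self):
        chi2, p = models.likelihood_ratio_test(-10.0, -10.0, 1)
        assert chi2 == 0.0 and p == 1.0

    def test_five_percent_point(self):
        # chi2 of 3.841 on 1 df sits at the 5% upper tail
        _, p = models.likelihood_ratio_test(-8.0795, -10.0, 1)
        assert p == pytest.approx(0.05, abs=5e-4)

    def test_strong_group_size_statistic(self):
        chi2, p = models.likelihood_ratio_test(-5.0, -9.755, 1)
        assert chi2 == pytest.approx(9.51)
        assert p == pytest.approx(0.002, abs=5e-4)

    def test_negative_chi2_warns_and_clamps(self):
        with pytest.warns(UserWarning, match="convergence"):
            chi2, p = models.likelihood_ratio_test(-10.0, -9.0, 1)
        assert chi2 == 0.0 and p == 1.0


class TestConditionalR2:
    @pytest.mark.parametrize(
        "vf, vr, ve, expected", [(1, 1, 2, 0.5), (0, 0, 1, 0.0), (1, 0, 0, 1.0)]
    )
    def test_identities(self, vf, vr, ve, expected):
        assert models.conditional_r2(vf, vr, ve) == pytest.approx(expected)

    def test_marginal_excludes_random(self):
        assert models.conditional_r2(1, 1, 2, marginal=True) == pytest.approx(0.25)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            models.conditional_r2(0, 0, 0)


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1, 2, 3, 4, 5]
        rho_up, _ = models.spearman_rho(x, [10, 20, 30, 40, 50])
        rho_dn, _ = models.spearman_rho(x, [50, 40, 30, 20, 10])
        assert rho_up == pytest.approx(1.0)
        assert rho_dn == pytest.approx(-1.0)

    def test_matches_rank_difference_formula(self, rng):
        """For 9 untied pairs, ρ must equal 1 − 6Σd²/(n(n²−1))."""
        x = rng.permutation(9).astype(float)
        y = rng.permutation(9).astype(float)
        d = stats.rankdata(x) - stats.rankdata(y)
        oracle = 1 - 6 * np.sum(d**2) / (9 * (81 - 1))
        rho, _ = models.spearman_rho(x, y)
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_exact_p_matches_enumeration_at_small_n(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        rho, p = models.spearman_rho(x, y)
        # brute-force the permutation distribution independently
        import itertools

        xr = stats.rankdata(x)
        yr = stats.rankdata(y)
        obs = abs(np.corrcoef(xr, yr)[0, 1])
        hits = total = 0
        for perm in itertools.permutations(yr):
            total += 1
            if abs(np.corrcoef(xr, perm)[0, 1]) >= obs - 1e-12:
                hits += 1
        assert p == pytest.approx(hits / total, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            models.spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])


class TestLinearModel:
    def test_exact_linear_fit_flags_infinite_f(self):
        table = pd.DataFrame({"x": np.arange(10.0)})
        table["y"] = 2.0 + 3.0 * table.x
        res = models.fit_linear_model(table, "y", ["x"])
        stat, _, p, kind = res.test("x")
        assert kind == "F" and np.isinf(stat) and p == 0.0 and res.flagged

    def test_overparameterised_design_rejected(self, rng):
        table = pd.DataFrame(
            rng.normal(size=(10, 10)), columns=[f"x{i}" for i in range(9)] + ["y"]
        )
        with pytest.raises(ValueError):
            models.fit_linear_model(table, "y", [f"x{i}" for i in range(9)])

    def test_f_equals_squared_t_for_single_term(self, rng):
        table = pd.DataFrame({"x": rng.normal(size=40)})
        table["y"] = 1.0 + 0.5 * table.x + rng.normal(size=40)
        res = models.fit_linear_model(table, "y", ["x"])
        est, se = res.coefficient("x")
        stat, _, _, _ = res.test("x")
        assert stat == pytest.approx((est / se) ** 2, rel=1e-9)


def _lmm_table(rng, n_groups=25, per_group=6, slope=0.5, sd_group=1.0, sd_resid=0.7):
    rows = []
    for g in range(n_groups):
        b = rng.normal(0, sd_group)
        for _ in range(per_group):
            x = rng.normal()
            rows.append(
                {"g": f"g{g}", "x": x, "y": 1.0 + slope * x + b + rng.normal(0, sd_resid)}
            )
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_recovers_known_slope(self, rng):
        table = _lmm_table(rng)
        res = models.fit_lmm(table, "y", ["x"], ["g"])
        est, se = res.coefficient("x")
        assert est == pytest.approx(0.5, abs=3 * se)
        assert 0 <= res.r2_marginal <= res.r2_conditional <= 1
        stat, df, p, kind = res.test("x")
        assert kind == "LRT" and df == 1 and p < 1e-6

    def test_every_fixed_term_gets_one_test(self, rng):
        table = _lmm_table(rng)
        table["z"] = rng.normal(size=len(table))
        res = models.fit_lmm(table, "y", ["x", "z"], ["g"])
        assert [t[0] for t in res.tests] == ["x", "z"]

    def test_missing_values_rejected(self, rng):
        table = _lmm_table(rng)
        table.loc[0, "x"] = np.nan
        with pytest.raises(models.MissingDataError):
            models.fit_lmm(table, "y", ["x"], ["g"])

    def test_single_level_grouping_rejected(self, rng):
        table = _lmm_table(rng, n_groups=1)
        with pytest.raises(ValueError):
            models.fit_lmm(table, "y", ["x"], ["g"])

    def test_lrt_matches_ols_loglik_for_nested_models(self, rng):
        """With trivial random structure the LRT must equal the analytic OLS one."""
        import statsmodels.formula.api as smf

        table = _lmm_table(rng, n_groups=30, per_group=4, sd_group=0.0)
        full = smf.ols("y ~ x", table).fit()
        reduced = smf.ols("y ~ 1", table).fit()
        chi2, _ = models.likelihood_ratio_test(full.llf, reduced.llf, 1)
        assert chi2 == pytest.approx(2 * (full.llf - reduced.llf), abs=1e-6)
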