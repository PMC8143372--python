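import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasmacna import datasets
from plasmacna.stats import (
    StatsInputError,
    SurvivalRecord,
    apply_censor_policy,
    chi_square_2x2,
    cox_fit,
    cox_partial_likelihood_score,
    fisher_exact_2x2,
    km_median,
    logrank_test,
    mann_whitney_u,
    spearman_rho,
    stepwise_backward,
)


class TestChiSquare:
    def test_response_table_reproduces_008(self):
        stat, p = chi_square_2x2([[17, 4], [5, 5]])
        assert round(p, 2) == 0.08

    def test_homogeneous_table(self):
        stat, p = chi_square_2x2([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_diagonal_table_statistic(self):
        stat, _ = chi_square_2x2([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(StatsInputError):
            chi_square_2x2([[0, 0], [5, 5]])

    @given(st.tuples(*[st.integers(1, 30)] * 4))
    @settings(max_examples=50, derandomize=True)
    def test_closed_form_identity(self, cells):
        a, b, c, d = cells
        stat, _ = chi_square_2x2([[a, b], [c, d]])
        n = a + b + c + d
        want = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert stat == pytest.approx(want, rel=1e-12)


def fisher_oracle(a, b, c, d):
    """Full hypergeometric enumeration over tables with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_row_swap_invariance(self):
        assert fisher_exact_2x2([[1, 9], [9, 1]]) == pytest.approx(
            fisher_exact_2x2([[9, 1], [1, 9]]))

    @given(st.tuples(*[st.integers(0, 10)] * 4))
    @settings(max_examples=60, derandomize=True)
    def test_matches_brute_force_enumeration(self, cells):
        a, b, c, d = cells
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            return
        assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
            fisher_oracle(a, b, c, d), abs=1e-9)


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        _, p = mann_whitney_u([1.0, 1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_fully_separated_small_groups_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6], alternative="less")
        assert u == 0.0
        assert p == pytest.approx(1 / 20)

    def test_cohort_pre_vs_post_tf_not_significant(self):
        mut = datasets.load_mutation_table()
        _, p = mann_whitney_u(apply_censor_policy(mut.pre_tf),
                              apply_censor_policy(mut.post_tf))
        assert p > 0.05


class TestSpearman:
    def test_monotone_pairs(self):
        rho, _ = spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_rho([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(StatsInputError):
            spearman_rho([1, 2, 3, 4], [1, 2, 3])

    def test_cohort_copies_versus_tf(self):
        dd = datasets.load_ddpcr_table()
        rho, p = spearman_rho(dd.activating_copies_per_ml.astype(float), dd.tf)
        assert rho == pytest.approx(0.46, abs=0.02)
        assert p < 0.01


class TestKaplanMeier:
    def test_common_event_time_is_median(self):
        res = km_median([5, 5, 5], [1, 1, 1])
        assert res.median == 5

    def test_four_distinct_events(self):
        # S(1)=.75, S(2)=.50 -> earliest time with S <= 0.5 is 2
        res = km_median([1, 2, 3, 4], [1, 1, 1, 1])
        assert res.median == 2

    def test_all_censored_median_undefined(self):
        res = km_median([3, 4, 5], [0, 0, 0])
        assert not res.median_defined

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 40)
        res = km_median(t, np.ones(40))
        for time, surv in res.curve.itertuples(index=False):
            assert surv == pytest.approx((t > time).mean(), abs=1e-12)


class TestLogrank:
    def test_identical_groups_zero_statistic(self):
        stat, p = logrank_test([1, 2, 3], [1, 1, 1], [1, 2, 3], [1, 1, 1])
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_separated_groups(self):
        # risk-set tally for a={1,2,3}, b={10,11,12}, all events:
        # O_a=3, E_a=0.5+0.4+0.25, V=0.25+0.24+0.1875
        e_a = 0.5 + 0.4 + 0.25
        v = 45 / 180 + 24 / 100 + 9 / 48
        want = (3 - e_a) ** 2 / v
        stat, _ = logrank_test([1, 2, 3], [1, 1, 1], [10, 11, 12], [1, 1, 1])
        assert stat == pytest.approx(want, rel=1e-9)

    def test_no_events_p_one(self):
        stat, p = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert p == 1.0


def _exponential_cohort(n, hr, seed, censor=40.0):
    rng = np.random.default_rng(seed)
    group = rng.integers(0, 2, n)
    rate = 0.1 * np.where(group == 1, hr, 1.0)
    t = rng.exponential(1 / rate)
    return pd.DataFrame({
        "time": np.minimum(t, censor).clip(1e-6),
        "event": (t <= censor).astype(int),
        "group": group,
    })


class TestCox:
    def test_recovers_simulated_hazard_ratio(self):
        df = _exponential_cohort(500, 3.33, seed=1)
        res = cox_fit(df, ["group"])
        assert res.converged
        assert res.hr("group") == pytest.approx(3.33, rel=0.15)
        assert res.table.loc["group", "ci_low"] < res.hr("group") < res.table.loc["group", "ci_high"]

    def test_score_vanishes_at_reported_optimum(self):
        df = _exponential_cohort(300, 2.0, seed=2)
        res = cox_fit(df, ["group"])
        score = cox_partial_likelihood_score(df, ["group"],
                                             np.log([res.hr("group")]))
        assert np.abs(score).max() < 1e-6

    def test_null_covariate_ci_coverage(self):
        covered = 0
        for i in range(100):
            df = _exponential_cohort(400, 1.0, seed=100 + i)
            res = cox_fit(df, ["group"])
            covered += res.table.loc["group", "ci_low"] <= 1 <= res.table.loc["group", "ci_high"]
        assert covered >= 93

    def test_constant_covariate_rejected(self):
        df = _exponential_cohort(50, 1.0, seed=3).assign(group=1)
        with pytest.raises(StatsInputError):
            cox_fit(df, ["group"])

    def test_survival_record_validation(self):
        with pytest.raises(StatsInputError):
            SurvivalRecord(time=0.0, event=True)
        records = [SurvivalRecord(float(i + 1), True, {"x": i % 2}) for i in range(20)]
        res = cox_fit(records, ["x"])
        assert res.converged


class TestStepwise:
    def test_p_remove_one_returns_full_model(self):
        df = _exponential_cohort(200, 2.0, seed=4)
        rng = np.random.default_rng(4)
        df["noise"] = rng.normal(size=len(df))
        res = stepwise_backward(df, ["group", "noise"], p_remove=1.0)
        assert res.retained == ("group", "noise")

    def test_all_null_covariates_may_empty_out(self):
        rng = np.random.default_rng(5)
        df = _exponential_cohort(200, 1.0, seed=5)
        df["noise"] = rng.normal(size=len(df))
        res = stepwise_backward(df, ["group", "noise"], p_remove=0.001)
        assert set(res.retained) <= {"group", "noise"}
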