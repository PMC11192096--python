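"""Statistical engine: KM, log-rank, epochs, earnings, ratings, exact tests."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import threatdyn as td
from threatdyn.analysis import rank_sum_test, exact_binomial_p
from threatdyn.cohort import RECORD_COLUMNS


def make_records(rows):
    """rows: (participant, condition, outcome, time) testing records."""
    data = [(pid, i, cond, "testing", out, t, t, np.nan, np.nan)
            for i, (pid, cond, out, t) in enumerate(rows)]
    return pd.DataFrame(data, columns=RECORD_COLUMNS)


class TestKaplanMeier:
    def test_two_escapes_no_censoring_by_hand(self):
        rec = make_records([(0, "early", "escape", 1), (1, "early", "escape", 2)])
        km = td.kaplan_meier(rec, "early")
        np.testing.assert_allclose(km.survival, [0.5, 0.0])

    def test_all_shocks_curve_stays_at_one(self):
        rec = make_records([(0, "early", "shock", t) for t in (3, 5, 9)])
        km = td.kaplan_meier(rec, "early")
        np.testing.assert_array_equal(km.survival, [1, 1, 1])
        assert km.censored.sum() == 3

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        times = rng.integers(0, 20, size=60)
        rec = make_records([(0, "early", "escape", int(t)) for t in times])
        km = td.kaplan_meier(rec, "early")
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx(np.mean(times > t))

    def test_matches_lifelines_with_censoring(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(1)
        times = rng.integers(0, 15, size=80)
        escaped = rng.random(80) < 0.6
        rec = make_records([(0, "early", "escape" if e else "shock", int(t))
                            for t, e in zip(times, escaped)])
        km = td.kaplan_meier(rec, "early")
        kmf = lifelines.KaplanMeierFitter().fit(times, event_observed=escaped)
        ours = dict(zip(km.times, km.survival))
        for t, s in kmf.survival_function_["KM_estimate"].items():
            if t in ours:
                assert ours[t] == pytest.approx(s)


class TestLogRank:
    def test_group_against_itself_is_zero(self):
        rec = make_records([(0, "early", "escape", t) for t in (1, 4, 7, 7, 9)]
                           + [(0, "early", "shock", 5)])
        chi2, p = td.log_rank(rec, rec.copy())
        assert chi2 == 0.0
        assert p == 1.0

    def test_symmetric_in_group_labels(self):
        a = make_records([(0, "early", "escape", t) for t in (1, 2, 5, 9)])
        b = make_records([(0, "late", "escape", t) for t in (3, 6, 7)]
                         + [(0, "late", "shock", 4)])
        chi_ab, _ = td.log_rank(a, b)
        chi_ba, _ = td.log_rank(b, a)
        assert chi_ab == pytest.approx(chi_ba)

    def test_extreme_separation_is_significant(self):
        early = make_records([(i, "early", "escape", 1) for i in range(20)])
        late = make_records([(i, "late", "escape", 29) for i in range(20)])
        chi2, p = td.log_rank(early, late)
        assert chi2 > 30
        assert p < 0.005

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(2)
        ta, tb = rng.integers(0, 20, 50), rng.integers(3, 25, 50)
        ea, eb = rng.random(50) < 0.7, rng.random(50) < 0.7
        a = make_records([(0, "early", "escape" if e else "shock", int(t))
                          for t, e in zip(ta, ea)])
        b = make_records([(0, "late", "escape" if e else "shock", int(t))
                          for t, e in zip(tb, eb)])
        chi2, p = td.log_rank(a, b)
        ref = lifelines.statistics.logrank_test(ta, tb, ea, eb)
        assert chi2 == pytest.approx(ref.test_statistic)
        assert p == pytest.approx(ref.p_value)

    def test_group_without_events_rejected(self):
        a = make_records([(0, "early", "escape", 1)])
        b = make_records([(0, "late", "shock", 2)])
        with pytest.raises(ValueError):
            td.log_rank(a, b)


class TestEpochs:
    def test_unanimous_escape_gives_proportion_one(self):
        rows = ([(i, "early", "escape", 7) for i in range(5)]
                + [(i, "late", "shock", 20) for i in range(5)])
        stats_list = td.epoch_avoidance(make_records(rows), epochs=[(6, 10)])
        assert stats_list[0].mean_early == 1.0
        assert stats_list[0].mean_late == 0.0

    def test_identical_behavior_gives_null_t(self):
        rows = []
        for i in range(8):
            for cond in ("early", "late"):
                rows += [(i, cond, "escape", 8), (i, cond, "shock", 20)]
        st_ = td.epoch_avoidance(make_records(rows), epochs=[(6, 10)])[0]
        assert st_.t_stat == pytest.approx(0.0)
        assert st_.p_value == pytest.approx(1.0)

    def test_trials_ending_before_epoch_do_not_enter(self):
        rows = [(0, "early", "escape", 2), (0, "early", "escape", 8),
                (0, "late", "escape", 8)]
        st_ = td.epoch_avoidance(make_records(rows), epochs=[(6, 10)])[0]
        # the t=2 escape never entered the epoch
        np.testing.assert_array_equal(st_.prop_early, [1.0])

    def test_empty_epoch_entry_rejected(self):
        rec = make_records([(0, "early", "escape", 1), (0, "late", "shock", 2)])
        with pytest.raises(ValueError):
            td.epoch_avoidance(rec, epochs=[(20, 25)])


class TestEarnings:
    def test_identical_earnings_zero_difference(self):
        rows = [(i, c, "escape", 10) for i in range(6) for c in ("early", "late")]
        res = td.earnings_comparison(make_records(rows))
        assert res.pct_difference == 0.0
        assert res.t_stat == 0.0

    def test_total_loss_is_hundred_percent(self):
        rows = ([(i, "early", "escape", 0) for i in range(6)]
                + [(i, "late", "escape", 10) for i in range(6)])
        res = td.earnings_comparison(make_records(rows))
        assert res.pct_difference == pytest.approx(100.0)

    def test_missing_condition_rejected(self):
        rec = make_records([(0, "early", "escape", 5), (1, "late", "shock", 9),
                            (1, "early", "escape", 3)])
        with pytest.raises(ValueError):
            td.earnings_comparison(rec)


class TestRatingAssociation:
    def test_noiseless_linear_rating_recovers_gain_exactly(self, default_pair):
        from threatdyn.analysis import _regressor_lookup
        lookup = _regressor_lookup(default_pair, "hazard")
        gain = 7.0
        rows = []
        i = 0
        rng = np.random.default_rng(0)
        for pid in range(6):
            for cond in ("early", "late"):
                for _ in range(6):
                    t = int(rng.integers(0, 24))
                    rows.append((pid, i, cond, "testing", "escape", t, t,
                                 gain * lookup[cond][t], t))
                    i += 1
        rec = pd.DataFrame(rows, columns=RECORD_COLUMNS)
        res = td.rating_association(rec, default_pair, "hazard")
        np.testing.assert_allclose(res.slopes, gain, atol=1e-9)
        assert res.p_value < 1e-6

    def test_pure_noise_ratings_are_calibrated(self, default_pair):
        """Type-I error of the two-stage slope test is near nominal."""
        rng = np.random.default_rng(10)
        rejections = 0
        n_reps = 400
        for _ in range(n_reps):
            rows = []
            i = 0
            for pid in range(10):
                for cond in ("early", "late"):
                    for _ in range(5):
                        t = int(rng.integers(0, 24))
                        rows.append((pid, i, cond, "testing", "escape", t, t,
                                     rng.normal(5, 1), t))
                        i += 1
            rec = pd.DataFrame(rows, columns=RECORD_COLUMNS)
            res = td.rating_association(rec, default_pair, "hazard",
                                        include_shock_covariate=False)
            rejections += res.p_value < 0.05
        rate = rejections / n_reps
        # 99% binomial band around .05 for 400 replicates
        assert 0.05 - 2.576 * np.sqrt(0.05 * 0.95 / n_reps) < rate \
            < 0.05 + 2.576 * np.sqrt(0.05 * 0.95 / n_reps)

    def test_subjects_with_few_ratings_dropped_with_warning(self, default_pair):
        rows = [(0, 0, "early", "testing", "escape", 5, 5, 3.0, 5),
                (0, 1, "early", "testing", "escape", 6, 6, 3.0, 6)]
        rows += [(1, i, "early", "testing", "escape", 5 + i % 3, 5, 3.0, 5 + i % 3)
                 for i in range(2, 8)]
        rec = pd.DataFrame(rows, columns=RECORD_COLUMNS)
        with pytest.warns(UserWarning, match="dropped"):
            res = td.rating_association(rec, default_pair, "hazard",
                                        include_shock_covariate=False)
        assert res.n_dropped == 1
        assert res.n_subjects == 1

    def test_hazard_regressor_beats_probability_on_hazard_driven_cohort(
            self, default_pair):
        """Ratings generated from the learned hazard fit the true-hazard
        regressor better than P(Threat) plus a condition term."""
        res = td.simulate_cohort(default_pair, n_participants=42,
                                 rating_every=2, rng=2024)
        hz = td.rating_association(res.records, default_pair, "hazard")
        pr = td.rating_association(res.records, default_pair, "probability",
                                   include_condition=True)
        assert abs(hz.t_stat) > abs(pr.t_stat)


class TestForcedChoice:
    def test_nineteen_of_twentyone_matches_tail_sum_oracle(self):
        k, n, p = td.forced_choice_test(["early"] * 19 + ["late"] * 2)
        oracle = 2 * (comb(21, 19) + comb(21, 20) + comb(21, 21)) / 2 ** 21
        assert p == pytest.approx(oracle)
        assert p == pytest.approx(2.2e-4, rel=0.01)
        assert p < 0.001

    def test_even_split_is_p_one(self):
        _, _, p = td.forced_choice_test(["early"] * 10 + ["late"] * 10)
        assert p == 1.0

    def test_unanimous_choice_closed_form(self):
        _, _, p = td.forced_choice_test(["early"] * 21)
        assert p == pytest.approx(2 * 2.0 ** -21)

    @pytest.mark.parametrize("k,n", [(3, 10), (7, 12), (12, 21), (19, 21)])
    def test_matches_scipy_for_fair_coin(self, k, n):
        # symmetric p=1/2: doubling the smaller tail equals scipy's method
        assert exact_binomial_p(k, n) == pytest.approx(
            stats.binomtest(k, n, 0.5).pvalue)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            td.forced_choice_test([])


class TestRankSum:
    def test_complete_separation_exact_p(self):
        x, y = [6, 7, 8, 9, 10], [1, 2, 3, 4, 5]
        u, p = rank_sum_test(x, y)
        assert u == 25.0
        assert p == pytest.approx(2 / comb(10, 5))

    def test_identical_sets_p_one(self):
        u, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_exact_p_matches_brute_force_enumeration_with_ties(self):
        x, y = [2.0, 5.0, 5.0, 9.0], [1.0, 2.0, 5.0, 7.0]
        u_obs, p_obs = rank_sum_test(x, y)
        pooled = np.asarray(x + y)
        ranks = stats.rankdata(pooled)
        nx = len(x)
        mu = nx * len(y) / 2
        us = [ranks[list(c)].sum() - nx * (nx + 1) / 2
              for c in itertools.combinations(range(len(pooled)), nx)]
        p_ref = np.mean([abs(u - mu) >= abs(u_obs - mu) - 1e-12 for u in us])
        assert p_obs == pytest.approx(p_ref)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=6), rng.normal(1.0, size=5)
        u, p = rank_sum_test(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_large_sample_normal_approx_close_to_scipy(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=25), rng.normal(0.5, size=25)
        _, p = rank_sum_test(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=0.15)


class TestFinalTrial:
    def base_records(self, ratings_early, ratings_late):
        rows = []
        i = 0
        for pid, (re_, rl) in enumerate(zip(ratings_early, ratings_late)):
            rows.append((pid, i, "early", "final", "shock", 20, 0, re_, 20))
            rows.append((pid, i + 1, "late", "final", "shock", 25, 0, rl, 25))
            i += 2
        return pd.DataFrame(rows, columns=RECORD_COLUMNS)

    def test_identical_rating_sets_p_one(self):
        rec = self.base_records([3, 4, 5], [3, 4, 5])
        res = td.final_trial_comparison(rec)
        assert res.p_value == 1.0

    def test_separated_ratings_detected(self):
        rec = self.base_records([6, 7, 8, 9, 10], [1, 2, 3, 4, 5])
        res = td.final_trial_comparison(rec)
        assert res.u_stat == 25.0
        assert res.p_value == pytest.approx(2 / comb(10, 5))
        assert res.mean_diff == pytest.approx(5.0)

    def test_hazard_cohort_rates_early_final_trial_higher(self, default_pair):
        res = td.simulate_cohort(default_pair, n_participants=42, rng=31)
        ft = td.final_trial_comparison(res.records)
        assert ft.mean_diff > 0
        assert ft.resid_mean_diff > 0

    def test_missing_final_ratings_rejected(self):
        rec = make_records([(0, "early", "escape", 5)])
        with pytest.raises(ValueError):
            td.final_trial_comparison(rec)
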