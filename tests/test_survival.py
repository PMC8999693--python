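import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from lifelines import KaplanMeierFitter
from scipy import stats

import arvcrisk as av


class TestKaplanMeier:
    def test_no_censoring_closed_form(self):
        curve = av.kaplan_meier(([1, 2, 3], [1, 1, 1]))
        assert curve.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert curve.at_risk.tolist() == [3, 2, 1]

    def test_hand_product_limit_with_censoring(self):
        # event at 1 (3 at risk), censored at 2, event at 3 (1 at risk)
        curve = av.kaplan_meier(([1, 2, 3], [1, 0, 1]))
        assert curve.event_times.tolist() == [1, 3]
        assert curve.survival == pytest.approx([2 / 3, 0.0])

    def test_all_censored_is_flat_one(self):
        curve = av.kaplan_meier(([1, 2, 3], [0, 0, 0]))
        assert curve.total_events == 0
        assert curve.survival_at(2.5) == 1.0
        assert curve.variance_at(2.5) == 0.0

    def test_events_precede_censorings_at_ties(self):
        # censoring at t=1 stays in the risk set for the event at t=1
        curve = av.kaplan_meier(([1, 1, 2], [1, 0, 1]))
        assert curve.survival == pytest.approx([2 / 3, 0.0])

    def test_record_interface(self):
        records = [av.FollowUpRecord(1, 1), av.FollowUpRecord(2, 0)]
        assert av.kaplan_meier(records).survival == pytest.approx([0.5])

    @pytest.mark.parametrize("bad", [([], []), ([0.0, 1.0], [1, 1]), ([1.0], [2])])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            av.kaplan_meier(bad)

    @given(
        times=st.lists(st.integers(1, 8).map(float), min_size=1, max_size=40)
    )
    @settings(derandomize=True, deadline=None)
    def test_equals_one_minus_ecdf_without_censoring(self, times):
        t = np.asarray(times)
        curve = av.kaplan_meier((t, np.ones_like(t, dtype=int)))
        for u in [0.5, 1.0, 2.5, 4.0, 8.0]:
            assert curve.survival_at(u) == pytest.approx((t > u).mean(), abs=1e-12)

    def test_matches_lifelines_on_censored_data(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(3.0, size=200)
        e = (rng.random(200) < 0.7).astype(int)
        curve = av.kaplan_meier((t, e))
        kmf = KaplanMeierFitter().fit(t, e)
        ours = [curve.survival_at(u) for u in curve.event_times]
        theirs = kmf.survival_function_at_times(curve.event_times).to_numpy()
        assert ours == pytest.approx(theirs, abs=1e-10)
        # CI cross-check (both use the log(-log) / exponential-Greenwood transform)
        ci = kmf.confidence_interval_survival_function_
        inner = curve.survival > 0  # final S=0 step has no finite transform
        theirs_lo = ci.iloc[:, 0].reindex(curve.event_times[inner]).to_numpy()
        theirs_up = ci.iloc[:, 1].reindex(curve.event_times[inner]).to_numpy()
        assert curve.ci_lower[inner] == pytest.approx(theirs_lo, abs=1e-8)
        assert curve.ci_upper[inner] == pytest.approx(theirs_up, abs=1e-8)

    def test_greenwood_variance_hand_value(self):
        curve = av.kaplan_meier(([1, 2, 3, 4], [1, 0, 1, 0]))
        # S(1)=3/4: var = (3/4)^2 * [1/(4*3)] ; S(3)=3/8: += 1/(2*1)
        assert curve.greenwood_var[0] == pytest.approx((3 / 4) ** 2 * (1 / 12))
        assert curve.greenwood_var[1] == pytest.approx((3 / 8) ** 2 * (1 / 12 + 1 / 2))


class TestEventRate:
    @pytest.fixture
    def curve(self):
        return av.kaplan_meier(([1, 2, 3], [1, 1, 1]))

    def test_step_lookup(self, curve):
        assert av.event_rate_at(curve, 2).rate == pytest.approx(2 / 3)

    def test_time_origin(self, curve):
        est = av.event_rate_at(curve, 0)
        assert est.rate == 0.0 and est.ci == (0.0, 0.0)

    def test_right_continuous_between_steps(self, curve):
        assert av.event_rate_at(curve, 1.5).rate == pytest.approx(1 / 3)

    def test_extrapolation_flagged(self, curve):
        est = av.event_rate_at(curve, 10)
        assert est.extrapolated and est.rate == pytest.approx(1.0)

    def test_ci_is_ordered_and_bounded(self):
        curve = av.kaplan_meier((np.arange(1, 21, dtype=float), [1] * 10 + [0] * 10))
        est = av.event_rate_at(curve, 5)
        assert 0.0 <= est.ci[0] <= est.rate <= est.ci[1] <= 1.0


class TestLogRank:
    def test_identical_groups_are_null(self):
        g = ([1, 2, 3], [1, 1, 0])
        res = av.log_rank_test(g, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_four_patient_example(self):
        # events at 1,2 (group a) vs 3,4 (group b):
        # O_a - E_a = 2 - (1/2 + 1/3), V = 1/4 + 2/9 -> chi2 = 2.88235...
        res = av.log_rank_test(([1, 2], [1, 1]), ([3, 4], [1, 1]))
        assert res.statistic == pytest.approx(2.8823529411764715, abs=1e-9)
        assert res.p_value == pytest.approx(0.08955507441364244, abs=1e-9)

    def test_label_swap_invariance(self):
        a, b = ([1, 3, 5], [1, 0, 1]), ([2, 4, 6, 8], [1, 1, 0, 1])
        r1, r2 = av.log_rank_test(a, b), av.log_rank_test(b, a)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
        assert 0.0 < r1.p_value <= 1.0

    def test_no_events_anywhere(self):
        res = av.log_rank_test(([1, 2], [0, 0]), ([3], [0]))
        assert res == av.LogRankResult(0.0, 1.0)

    def test_type_one_error_under_null(self):
        """Equal exponential hazards: rejection rate at 0.05 stays nominal."""
        rng = np.random.default_rng(42)
        reps, rejections = 400, 0
        for _ in range(reps):
            ta, tb = rng.exponential(2.0, 40), rng.exponential(2.0, 40)
            ca, cb = rng.uniform(0, 6, 40), rng.uniform(0, 6, 40)
            res = av.log_rank_test(
                (np.minimum(ta, ca), (ta <= ca).astype(int)),
                (np.minimum(tb, cb), (tb <= cb).astype(int)),
            )
            rejections += res.p_value < 0.05
        # binomial(400, 0.05): +-3 sd around 20
        assert 7 <= rejections <= 33


class TestConcordance:
    def test_perfect_discrimination(self):
        times = [5, 4, 3, 2, 1]
        risks = [1, 2, 3, 4, 5]
        assert av.concordance_index(risks, (times, [1] * 5)) == 1.0

    def test_all_tied_scores(self):
        assert av.concordance_index([2, 2, 2], ([1, 2, 3], [1, 1, 1])) == 0.5

    def test_five_patient_censored_example(self, c_oracle):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        events = [1, 0, 1, 1, 0]
        risks = [0.9, 0.1, 0.5, 0.5, 0.2]
        expected = c_oracle(risks, times, events)
        assert av.concordance_index(risks, (times, events)) == pytest.approx(expected)

    def test_all_censored_is_undefined(self):
        with pytest.raises(av.ConcordanceUndefinedError):
            av.concordance_index([1, 2], ([1, 2], [0, 0]))

    @given(
        n=st.integers(2, 50),
        seed=st.integers(0, 10_000),
    )
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_matches_bruteforce_oracle(self, n, seed, c_oracle):
        rng = np.random.default_rng(seed)
        times = rng.integers(1, 10, size=n).astype(float)  # ties likely
        events = rng.integers(0, 2, size=n)
        risks = rng.integers(0, 5, size=n).astype(float)  # score ties likely
        try:
            expected = c_oracle(risks, times, events)
        except ValueError:
            with pytest.raises(av.ConcordanceUndefinedError):
                av.concordance_index(risks, (times, events))
            return
        assert av.concordance_index(risks, (times, events)) == pytest.approx(expected)

    def test_matches_lifelines_on_tie_free_data(self):
        from lifelines.utils import concordance_index as ll_c

        rng = np.random.default_rng(5)
        t = rng.exponential(2.0, 150)
        e = (rng.random(150) < 0.6).astype(int)
        r = rng.normal(size=150)
        assert av.concordance_index(r, (t, e)) == pytest.approx(ll_c(t, -r, e), abs=1e-12)

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(2.0, 100)
        e = np.ones(100, dtype=int)
        r = -t + rng.normal(scale=1.0, size=100)
        c, (lo, hi) = av.concordance_with_ci(r, (t, e), n_boot=200, rng=1)
        assert lo <= c <= hi and c > 0.5
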