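"""Kaplan-Meier, log-rank, RMST, median split, time-dependent ROC, per-gene KM."""

import numpy as np
import pytest

from nbsig import (
    gene_km,
    kaplan_meier,
    logrank_test,
    mean_survival,
    median_split,
    survival_at,
    td_roc,
)


class TestKaplanMeier:
    def test_complete_data(self):
        km = kaplan_meier([1, 2, 3, 4], [1, 1, 1, 1])
        np.testing.assert_allclose(km.survival, [0.75, 0.5, 0.25, 0.0])

    def test_censoring_hand_example(self):
        # subjects at 1 (event), 2 (censored), 3 (event):
        # S(1) = 2/3; at t=3 one at risk, one event -> S(3) = 0
        km = kaplan_meier([1, 2, 3], [1, 0, 1])
        np.testing.assert_allclose(km.times, [1, 3])
        np.testing.assert_allclose(km.survival, [2 / 3, 0.0])

    def test_all_censored_is_one(self):
        km = kaplan_meier([1, 2, 3], [0, 0, 0])
        assert survival_at(km, 2.5) == 1.0

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(2, 60)
        km = kaplan_meier(t, np.ones(60, int))
        for q in [0.5, 1.0, 2.0]:
            assert survival_at(km, q) == pytest.approx(np.mean(t > q))

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([-1, 2], [1, 1])


class TestSurvivalAt:
    def test_time_zero_is_one(self):
        km = kaplan_meier([1, 2], [1, 1])
        assert survival_at(km, 0) == 1.0

    def test_step_lookup(self):
        km = kaplan_meier([1, 2, 3, 4], [1, 1, 1, 1])
        assert survival_at(km, 2.5) == 0.5

    def test_right_continuous_at_event(self):
        km = kaplan_meier([1, 2, 3, 4], [1, 1, 1, 1])
        assert survival_at(km, 2) == 0.5  # post-drop value

    def test_beyond_last_observed_warns(self):
        km = kaplan_meier([1, 2], [1, 0])
        with pytest.warns(UserWarning, match="beyond"):
            survival_at(km, 10)


class TestMeanSurvival:
    def test_flat_curve(self):
        km = kaplan_meier([6, 7], [0, 0])  # no events before horizon
        assert mean_survival(km, 5) == 5.0

    def test_single_drop_rectangle(self):
        km = kaplan_meier([2.0], [1])
        assert mean_survival(km, 5) == 2.0

    def test_hand_integration(self):
        km = kaplan_meier([1, 2, 3, 4], [1, 1, 1, 1])
        assert mean_survival(km, 4) == pytest.approx(1 + 0.75 + 0.5 + 0.25)

    def test_bounded_by_horizon(self, rng):
        t = rng.exponential(1, 50)
        km = kaplan_meier(t, (rng.random(50) < 0.7).astype(int))
        assert 0 <= mean_survival(km, 5) <= 5


class TestLogRank:
    def test_identical_groups_null(self):
        g = ([1, 2, 3, 4], [1, 1, 0, 1])
        res = logrank_test([g, g])
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_label_symmetry(self):
        a = ([1, 2, 5], [1, 1, 0])
        b = ([3, 4, 6], [1, 0, 1])
        r1 = logrank_test([a, b])
        r2 = logrank_test([b, a])
        assert r1.chi_square == pytest.approx(r2.chi_square, abs=1e-12)

    def test_eight_subject_hand_oracle(self):
        # two groups of four; O-E and hypergeometric variance computed
        # step by step below, independently of the implementation
        ta, ea = np.array([1.0, 3.0, 5.0, 7.0]), np.array([1, 1, 0, 1])
        tb, eb = np.array([2.0, 4.0, 6.0, 8.0]), np.array([1, 0, 1, 1])
        time = np.r_[ta, tb]
        event = np.r_[ea, eb]
        group = np.r_[np.zeros(4), np.ones(4)]
        O = E = V = 0.0
        for t in sorted(time[event == 1]):
            at_risk = time >= t
            n = at_risk.sum()
            n1 = (at_risk & (group == 0)).sum()
            d = ((time == t) & (event == 1)).sum()
            d1 = ((time == t) & (event == 1) & (group == 0)).sum()
            O += d1
            E += d * n1 / n
            if n > 1:
                V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected_chi2 = (O - E) ** 2 / V
        res = logrank_test([(ta, ea), (tb, eb)])
        assert res.chi_square == pytest.approx(expected_chi2, abs=1e-10)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        t = rng.exponential(1, 80)
        e = (rng.random(80) < 0.7).astype(int)
        g = rng.integers(0, 3, 80)
        res = logrank_test([(t[g == k], e[g == k]) for k in range(3)])
        ref = multivariate_logrank_test(t, g, e)
        assert res.chi_square == pytest.approx(ref.test_statistic, abs=1e-8)
        assert res.p_value == pytest.approx(ref.p_value, abs=1e-8)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            logrank_test([([1, 2], [1, 1]), ([], [])])


class TestMedianSplit:
    def test_threshold_rule(self):
        assert list(median_split([1, 2, 3, 4], 2.5)) == ["low", "low", "high", "high"]

    def test_ties_go_low(self):
        assert list(median_split([2.0, 2.0], 2.0)) == ["low", "low"]

    def test_monotone_transform_invariance(self, rng):
        s = rng.normal(size=30)
        med = np.median(s)
        l1 = median_split(s, med)
        l2 = median_split(np.exp(s), np.exp(med))
        assert (l1 == l2).all()


def oracle_td_roc(scores, time, event, horizon):
    """Independent straight-line evaluation of the KM-weighted estimator."""

    def km(t_arr, e_arr, at):
        s = 1.0
        for tt in sorted(set(t_arr[e_arr == 1])):
            if tt > at:
                break
            n = np.sum(t_arr >= tt)
            d = np.sum((t_arr == tt) & (e_arr == 1))
            s *= 1 - d / n
        return s

    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    s_all = km(time, event, horizon)
    pts = []
    for c in np.concatenate([[-np.inf], np.unique(scores)]):
        high = scores > c
        p_high = high.mean()
        s_high = km(time[high], event[high], min(horizon, time[high].max())) if high.any() else 1.0
        s_low = km(time[~high], event[~high], min(horizon, time[~high].max())) if (~high).any() else 1.0
        tpr = (1 - s_high) * p_high / (1 - s_all)
        fpr = 1 - s_low * (1 - p_high) / s_all
        pts.append((min(max(fpr, 0), 1), min(max(tpr, 0), 1)))
    pts = sorted(pts) + [(1.0, 1.0)]
    pts = [(0.0, 0.0)] + pts
    xs, ys = zip(*pts)
    return np.trapezoid(ys, xs)


class TestTdRoc:
    def test_constant_score_auc_half(self):
        t = np.array([0.5, 1.5, 2.5, 3.5])
        assert td_roc(np.zeros(4), t, np.ones(4, int), 2.0).auc == pytest.approx(0.5)

    def test_perfect_marker_auc_one(self):
        t = np.array([0.2, 0.4, 0.6, 1.5, 2.0, 3.0])
        assert td_roc(-t, t, np.ones(6, int), 1.0).auc == pytest.approx(1.0)

    def test_ten_subject_censored_oracle(self):
        time = np.array([0.3, 0.6, 0.9, 1.2, 1.4, 1.8, 2.2, 2.6, 3.0, 3.5])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 1])
        scores = np.array([2.1, 1.7, 0.4, 1.1, -0.2, 0.9, -0.5, 0.3, -1.0, -1.4])
        res = td_roc(scores, time, event, 2.0)
        assert res.auc == pytest.approx(oracle_td_roc(scores, time, event, 2.0), abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        t = rng.exponential(1, 100)
        e = (rng.random(100) < 0.8).astype(int)
        s = rng.standard_normal(100)
        a1 = td_roc(s, t, e, 1.0).auc
        a2 = td_roc(np.tanh(s) * 7 + 2, t, e, 1.0).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_roc_curve_monotone_without_censoring(self, rng):
        t = rng.exponential(1, 60)
        s = rng.standard_normal(60)
        res = td_roc(s, t, np.ones(60, int), 1.0)
        # round away 1e-16 jitter so equal FPRs sort together
        fpr, tpr = res.fpr.round(9), res.tpr.round(9)
        order = np.lexsort((tpr, fpr))
        assert (np.diff(tpr[order]) >= 0).all()

    def test_no_events_before_horizon_rejected(self):
        t = np.array([2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="horizon|events"):
            td_roc(np.array([1.0, 2, 3]), t, np.array([1, 1, 1]), 1.0)


class TestGeneKm:
    def test_boundary_z_goes_low(self):
        time = np.r_[np.ones(5), 2 * np.ones(5)]
        event = np.ones(10, int)
        z = np.r_[np.zeros(5), np.ones(5)]  # z == 0 -> low group
        low, high, _ = gene_km(z, time, event)
        assert low.n_subjects == 5
        assert high.n_subjects == 5

    def test_one_sided_split_rejected(self):
        with pytest.raises(ValueError, match="one-sided"):
            gene_km(np.ones(6), np.arange(1.0, 7), np.ones(6, int))

    def test_planted_risk_gene_separates_survival(self, rng):
        n = 400
        z = rng.standard_normal(n)
        t = rng.exponential(1 / np.exp(1.0 * z))
        e = np.ones(n, int)
        low, high, lr = gene_km(z, t, e)
        horizon = np.percentile(t, 60)
        assert survival_at(high, horizon) < survival_at(low, horizon)
        assert lr.p_value < 0.01
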