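import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from matriscore.survival_stats import (
    best_cutpoint,
    cox_univariate,
    dichotomized_km,
    kaplan_meier,
    logrank_test,
)

from _reference import reference_logrank_two_group


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        km = kaplan_meier([1, 2, 3, 4], [0, 0, 0, 0])
        assert km(0) == 1.0 and km(10) == 1.0

    def test_all_events_closed_form(self):
        km = kaplan_meier([1, 2, 3], [1, 1, 1])
        assert km(1) == pytest.approx(2 / 3)
        assert km(2) == pytest.approx(1 / 3)
        assert km(3) == pytest.approx(0.0)

    def test_tied_events_factor(self):
        # 4 at risk, 2 events at t=1 -> S(1) = 1/2
        km = kaplan_meier([1, 1, 2, 2], [1, 1, 0, 0])
        assert km(1) == pytest.approx(0.5)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            kaplan_meier([-1, 2], [1, 1])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_monotone_and_starts_at_one(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        t = rng.exponential(10, n)
        e = rng.integers(0, 2, n)
        if e.sum() == 0:
            e[0] = 1
        km = kaplan_meier(t, e)
        assert km(0.0) == 1.0
        grid = km(np.sort(t))
        assert (np.diff(grid) <= 1e-12).all()


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 0, 1, 1, 1, 0, 1, 1]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        chi2, p, df = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert df == 1

    def test_hand_worked_toy_table(self):
        # A: (1+, 2, 3)   B: (1, 2+, 4)    "+" = censored
        t = [1, 2, 3, 1, 2, 4]
        e = [0, 1, 1, 1, 0, 1]
        g = [0, 0, 0, 1, 1, 1]
        chi2, p, df = logrank_test(t, e, g)
        expected = reference_logrank_two_group(t, e, g)
        assert chi2 == pytest.approx(expected, abs=1e-10)

    def test_matches_lifelines(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(21)
        t = rng.exponential(10, 80)
        e = rng.integers(0, 2, 80)
        e[0] = 1
        g = rng.integers(0, 3, 80)
        chi2, p, df = logrank_test(t, e, g)
        ll = multivariate_logrank_test(t, g, e)
        assert chi2 == pytest.approx(ll.test_statistic, rel=1e-8)
        assert df == 2

    def test_time_transform_invariance(self):
        rng = np.random.default_rng(22)
        t = rng.exponential(5, 50)
        e = rng.integers(0, 2, 50)
        e[:2] = 1
        g = rng.integers(0, 2, 50)
        chi2a, _, _ = logrank_test(t, e, g)
        chi2b, _, _ = logrank_test(np.exp(t / 10), e, g)  # monotone transform
        assert chi2a == pytest.approx(chi2b, abs=1e-10)

    def test_agrees_with_exhaustive_permutation_ordering(self):
        # on tiny inputs the chi2 ordering matches the exact permutation p
        rng = np.random.default_rng(23)
        t = rng.exponential(5, 8).round(2)
        e = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        datasets = []
        for labels in ([0, 0, 0, 0, 1, 1, 1, 1], [0, 1, 0, 1, 0, 1, 0, 1]):
            g = np.array(labels)
            chi2, _, _ = logrank_test(t, e, g)
            perm_more = sum(
                logrank_test(t, e, np.array(perm))[0] >= chi2 - 1e-12
                for perm in set(itertools.permutations(g))
            )
            perm_total = len(set(itertools.permutations(g)))
            datasets.append((chi2, perm_more / perm_total))
        chis, perm_ps = zip(*datasets)
        assert (chis[0] > chis[1]) == (perm_ps[0] < perm_ps[1]) or \
            chis[0] == pytest.approx(chis[1])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test([1, 2], [1, 1], [0, 0])

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(24)
        rejections = 0
        reps = 400
        for _ in range(reps):
            t = rng.exponential(10, 100)
            e = (t <= np.quantile(t, 0.8)).astype(int)
            t = np.minimum(t, np.quantile(t, 0.8))
            g = np.repeat([0, 1], 50)
            _, p, _ = logrank_test(t, e, g)
            rejections += p < 0.05
        assert 0.02 <= rejections / reps <= 0.08


class TestCoxUnivariate:
    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_univariate([1, 1, 1], [1, 2, 3], [1, 1, 1])

    def test_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(25)
        n = 2000
        x = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.05 * 2.0**x))
        fit = cox_univariate(x, t, np.ones(n, dtype=int))
        assert 1.85 <= fit.hr <= 2.15
        assert fit.ci95[0] < fit.hr < fit.ci95[1]
        assert fit.converged

    def test_score_test_equals_logrank_without_ties(self):
        rng = np.random.default_rng(26)
        n = 60
        x = rng.integers(0, 2, n)
        t = rng.exponential(10, n)  # continuous: no ties
        e = rng.integers(0, 2, n)
        e[:4] = 1
        fit = cox_univariate(x.astype(float), t, e)
        chi2, _, _ = logrank_test(t, e, x)
        assert fit.score_chi2 == pytest.approx(chi2, abs=1e-8)

    def test_matches_lifelines_beta_and_se(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(27)
        n = 300
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.5 * x)))
        c = np.quantile(t, 0.7)
        e = (t <= c).astype(int)
        t = np.minimum(t, c)
        fit = cox_univariate(x, t, e)
        cph = CoxPHFitter()
        cph.fit(pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e")
        assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-4)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], abs=1e-4)

    def test_location_invariance_and_scale_inverse(self):
        rng = np.random.default_rng(28)
        n = 150
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.4 * x)))
        e = np.ones(n, dtype=int)
        base = cox_univariate(x, t, e)
        shifted = cox_univariate(x + 100.0, t, e)
        scaled = cox_univariate(2.0 * x, t, e)
        assert base.beta == pytest.approx(shifted.beta, abs=1e-6)
        assert base.beta == pytest.approx(2.0 * scaled.beta, rel=1e-6)

    def test_monotone_likelihood_flagged_not_raised(self):
        # perfect separation: all events in one arm before the other starts
        t = np.concatenate([np.arange(1, 11), np.arange(100, 110)])
        e = np.ones(20, dtype=int)
        x = np.repeat([1.0, 0.0], 10)
        fit = cox_univariate(x, t, e)
        assert not fit.converged


class TestBestCutpoint:
    def test_recovers_planted_threshold(self):
        rng = np.random.default_rng(29)
        hits = 0
        reps = 30
        for _ in range(reps):
            n = 500
            s = rng.uniform(-1, 1, n)
            rate = 0.05 * np.where(s > 0, 2.0, 1.0)
            t = rng.exponential(1.0 / rate)
            cp = best_cutpoint(s, t, np.ones(n, dtype=int))
            hits += abs(cp.cutpoint) <= 0.15
        assert hits / reps >= 0.9

    def test_monotone_transform_same_partition(self):
        rng = np.random.default_rng(30)
        n = 60
        s = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.8 * s)))
        e = np.ones(n, dtype=int)
        cp1 = best_cutpoint(s, t, e)
        cp2 = best_cutpoint(s**3, t, e)
        assert ((s > cp1.cutpoint) == (s**3 > cp2.cutpoint)).all()

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            best_cutpoint(np.ones(20), np.arange(1, 21), np.ones(20, dtype=int))

    def test_minprop_respected(self):
        rng = np.random.default_rng(31)
        n = 100
        s = rng.normal(size=n)
        t = rng.exponential(10, n)
        cp = best_cutpoint(s, t, np.ones(n, dtype=int), minprop=0.2)
        assert min(cp.group_sizes) >= 20
        assert cp.group_sizes[0] + cp.group_sizes[1] == n

    def test_cutpoint_strictly_between_observed_values(self):
        rng = np.random.default_rng(32)
        s = rng.normal(size=50)
        t = rng.exponential(10, 50)
        cp = best_cutpoint(s, t, np.ones(50, dtype=int))
        below = s[s <= cp.cutpoint].max()
        above = s[s > cp.cutpoint].min()
        assert below < cp.cutpoint < above


class TestDichotomizedKm:
    def test_planted_hr_recovered_with_selection_bias_band(self):
        # the maximized cutpoint biases the HR upward, hence the asymmetric
        # band around the true value 2; the median over reps damps seed noise
        rng = np.random.default_rng(33)
        hrs, ps = [], []
        for _ in range(10):
            n = 500
            s = rng.uniform(-1, 1, n)
            rate = 0.05 * np.where(s > 0, 2.0, 1.0)
            t = rng.exponential(1.0 / rate)
            e = np.ones(n, dtype=int)
            cp = best_cutpoint(s, t, e)
            fit, p, km = dichotomized_km(s, cp.cutpoint, t, e)
            hrs.append(fit.hr)
            ps.append(p)
            assert set(km) == {"low", "high"}
        assert 1.7 <= np.median(hrs) <= 2.4
        assert max(ps) < 1e-4

    def test_negated_score_inverts_hr(self):
        rng = np.random.default_rng(34)
        n = 80
        s = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.6 * s)))
        e = np.ones(n, dtype=int)
        fit_a, _, _ = dichotomized_km(s, 0.0, t, e)
        fit_b, _, _ = dichotomized_km(-s, -0.0, t, e)
        assert fit_a.hr == pytest.approx(1.0 / fit_b.hr, abs=1e-8)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            dichotomized_km([1.0, 2.0, 3.0], 0.0, [1, 2, 3], [1, 1, 1])
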