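"""Peri-event firing statistics and reward-rate correlation machinery."""

import numpy as np
import pytest
from scipy import stats

from nsr import peth
from nsr.peth import (
    action_preference,
    build_peth,
    fisher_z_compare,
    outcome_contrast,
    per_trial_bin_rates,
    population_r_test,
    reward_rate_correlation,
    task_related_test,
    window_rates,
    WindowStats,
)


class TestBuildPeth:
    def test_no_spikes_gives_zero_peth(self):
        p = build_peth([], [1.0, 2.0, 3.0], span=(-0.5, 0.5))
        assert np.all(p.rate == 0) and np.all(p.raw_rate == 0)

    def test_one_spike_per_event_lands_in_event_bin(self):
        events = np.arange(1.0, 21.0)
        p = build_peth(events + 1e-6, events, span=(-0.5, 0.5))
        # Raw 20 ms bins: the bin starting at 0 holds one spike per trial.
        idx = np.argmin(np.abs(p.raw_bin_centers - 0.01))
        assert p.raw_rate[idx] == pytest.approx(1 / 0.02)
        assert p.raw_rate.sum() * 0.02 * p.n_trials == pytest.approx(events.size)

    def test_homogeneous_poisson_rate_recovered(self):
        rng = np.random.default_rng(3)
        rate, t_end = 10.0, 2000.0
        spikes = np.sort(rng.uniform(0, t_end, rng.poisson(rate * t_end)))
        events = np.arange(10.0, t_end - 10.0, 4.0)[:500]
        p = build_peth(spikes, events, span=(-1.0, 1.0))
        se = np.sqrt(rate / (events.size * 2.0))
        assert abs(p.rate.mean() - rate) < 3 * se

    def test_integration_and_smoothing_preserve_mean_rate(self):
        rng = np.random.default_rng(4)
        spikes = np.sort(rng.uniform(0, 500, 3000))
        events = np.arange(5.0, 495.0, 5.0)
        p = build_peth(spikes, events, span=(-1.0, 1.0))
        in_span = sum(
            np.count_nonzero((spikes >= ev - 1.0) & (spikes < ev + 1.0)) for ev in events
        )
        assert p.raw_rate.sum() * 0.02 == pytest.approx(in_span / events.size)
        assert p.rate.mean() == pytest.approx(p.raw_rate.mean(), rel=0.05)

    def test_empty_event_list_rejected(self):
        with pytest.raises(ValueError):
            build_peth([1.0], [], span=(-1.0, 1.0))


class TestTaskRelated:
    def _stats(self, baseline, window):
        return WindowStats(
            baseline=np.asarray(baseline, dtype=float),
            go=np.asarray(window, dtype=float),
            movement=np.asarray(window, dtype=float),
            outcome=np.asarray(window, dtype=float),
        )

    def test_identical_rates_not_significant(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(5, 100).astype(float)
        res = task_related_test(self._stats(base, base))
        assert res["testable"] and not res["task_related"]

    def test_doubled_rate_detected(self):
        rng = np.random.default_rng(1)
        res = task_related_test(
            self._stats(rng.poisson(2, 200).astype(float), rng.poisson(4, 200).astype(float))
        )
        assert res["task_related"]
        assert res["p"]["movement"] < 1e-6

    def test_single_trial_untestable(self):
        res = task_related_test(self._stats([2.0], [4.0]))
        assert not res["testable"]


class TestActionPreference:
    def test_ten_percent_difference_prefers_push(self):
        assert action_preference([10.0] * 20, [9.0] * 20) == "push"

    def test_two_percent_difference_is_none(self):
        assert action_preference([10.0] * 20, [9.8] * 20) == "none"

    def test_silent_unit_is_none(self):
        assert action_preference([0.0, 0.0], [0.0, 0.0]) == "none"

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError):
            action_preference([], [1.0])


class TestRewardRateCorrelation:
    def test_linear_coupling_recovered_with_positive_sign(self):
        rng = np.random.default_rng(5)
        rr = rng.choice([0, 0.2, 0.4, 0.6, 0.8, 1.0], 300)
        z = 2.0 * rr + rng.normal(0, 0.1, 300)
        res = reward_rate_correlation(z, rr)
        assert res.r > 0.9 and res.p < 1e-10

    def test_constant_activity_undefined(self):
        rr = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        res = reward_rate_correlation(np.ones(5), rr)
        assert not res.defined and np.isnan(res.r)

    def test_undefined_reward_rates_excluded(self):
        rr = np.array([np.nan] * 5 + [0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
        z = np.arange(11, dtype=float)
        res = reward_rate_correlation(z, rr)
        assert res.n_trials == 6

    def test_type_i_error_near_alpha(self):
        rng = np.random.default_rng(6)
        rr = rng.choice([0, 0.2, 0.4, 0.6, 0.8, 1.0], 200)
        hits = sum(
            reward_rate_correlation(rng.normal(0, 1, 200), rr).p < 0.05 for _ in range(500)
        )
        assert 0.02 <= hits / 500 <= 0.09

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            reward_rate_correlation([1.0, 2.0, 3.0], [0.2, 0.4, 0.6])


class TestPopulationTest:
    def test_symmetric_null_not_significant(self):
        rng = np.random.default_rng(7)
        r = rng.normal(0, 0.2, 40)
        r = np.concatenate([r, -r])  # exactly symmetric about 0
        assert population_r_test(r) > 0.9

    def test_consistent_positive_shift_detected(self):
        with pytest.warns(UserWarning):
            p = population_r_test([0.3] * 20)
        assert p < 0.05

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            population_r_test([0.3])


class TestFisherZ:
    def test_equal_correlations_give_zero(self):
        z, p = fisher_z_compare(0.4, 100, 0.4, 80)
        assert z == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_matches_independent_closed_form(self):
        z, p = fisher_z_compare(0.5, 50, 0.0, 50)
        z_expected = (np.arctanh(0.5) - np.arctanh(0.0)) / np.sqrt(1 / 47 + 1 / 47)
        p_expected = 2 * (1 - stats.norm.cdf(abs(z_expected)))
        assert z == pytest.approx(z_expected)
        assert p == pytest.approx(p_expected)

    def test_bonferroni_caps_at_one(self):
        # raw p = 0.5 at z ~ 0.674; m = 3 caps the product at 1.
        r = np.tanh(0.6745 * np.sqrt(2 / 47))
        _, p = fisher_z_compare(r, 50, 0.0, 50, m_comparisons=3)
        assert p == 1.0

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_compare(1.0, 50, 0.0, 50)
        with pytest.raises(ValueError):
            fisher_z_compare(0.5, 3, 0.0, 50)

    def test_agrees_with_permutation_comparison(self):
        # Simulated two-group comparison: Fisher z p vs shuffling group labels.
        rng = np.random.default_rng(8)
        n = 60
        x1 = rng.normal(0, 1, n)
        y1 = 0.5 * x1 + rng.normal(0, 1, n)
        x2 = rng.normal(0, 1, n)
        y2 = rng.normal(0, 1, n)
        r1 = stats.pearsonr(x1, y1)[0]
        r2 = stats.pearsonr(x2, y2)[0]
        _, p_fisher = fisher_z_compare(r1, n, r2, n)
        obs = abs(np.arctanh(r1) - np.arctanh(r2))
        pairs = np.vstack([np.column_stack([x1, y1]), np.column_stack([x2, y2])])
        count = 0
        n_shuffle = 2000
        for _ in range(n_shuffle):
            idx = rng.permutation(2 * n)
            a, b = pairs[idx[:n]], pairs[idx[n:]]
            ra = stats.pearsonr(a[:, 0], a[:, 1])[0]
            rb = stats.pearsonr(b[:, 0], b[:, 1])[0]
            count += abs(np.arctanh(ra) - np.arctanh(rb)) >= obs
        p_perm = count / n_shuffle
        se = np.sqrt(p_perm * (1 - p_perm) / n_shuffle) + 1e-3
        assert abs(p_fisher - p_perm) < 4 * se + 0.02


class TestOutcomeContrast:
    def test_identical_conditions_empty_mask(self):
        rng = np.random.default_rng(9)
        rates = rng.poisson(5, (50, 30)).astype(float)
        assert not outcome_contrast(rates, rates).any()

    def test_rate_difference_flagged_in_outcome_bins(self):
        rng = np.random.default_rng(10)
        a = rng.poisson(15 * 0.02, (200, 25)) / 0.02
        b = rng.poisson(5 * 0.02, (200, 25)) / 0.02
        mask = outcome_contrast(a, b)
        assert mask.mean() > 0.9

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            outcome_contrast(np.ones((1, 10)), np.ones((5, 10)))


class TestWindowRates:
    def test_counts_divided_by_width(self):
        spikes = [1.05, 1.10, 1.25, 2.05]
        rates = window_rates(spikes, [1.0, 2.0], (0.0, 0.3))
        np.testing.assert_allclose(rates, [3 / 0.3, 1 / 0.3])

    def test_per_trial_bin_rates_match_histogram(self):
        rng = np.random.default_rng(11)
        spikes = np.sort(rng.uniform(0, 100, 500))
        events = [10.0, 50.0]
        mat = per_trial_bin_rates(spikes, events, (-0.5, 0.5))
        assert mat.shape == (2, 50)
        for i, ev in enumerate(events):
            total = np.count_nonzero((spikes >= ev - 0.5) & (spikes < ev + 0.5))
            assert mat[i].sum() * 0.02 == pytest.approx(total)
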