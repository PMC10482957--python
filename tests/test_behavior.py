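"""Behavioral statistics: reward rate, choice regression, switch curves, onset detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nsr import behavior, task_sim
from nsr.behavior import NoMovementDetected
from nsr.task_sim import PolicyParams

from conftest import make_trial


class TestRewardRate:
    def test_all_rewarded_history_gives_one(self):
        rr = behavior.compute_reward_rate([1, 1, 1, 1, 1, 0])
        assert rr.values[5] == 1.0

    def test_no_rewards_history_gives_zero(self):
        rr = behavior.compute_reward_rate([0, 0, 0, 0, 0, 1])
        assert rr.values[5] == 0.0

    def test_two_of_five_gives_point_four(self):
        rr = behavior.compute_reward_rate([1, 0, 1, 0, 0, 0])
        assert rr.values[5] == pytest.approx(0.4)

    def test_current_trial_excluded_and_warmup_flagged(self):
        rr = behavior.compute_reward_rate([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        assert not rr.valid[:5].any()
        assert rr.valid[5:].all()
        assert rr.valid_from == 5
        # Trial 6 sees trials 1-5 (four rewards), not its own outcome.
        assert rr.values[6] == pytest.approx(0.8)

    def test_short_sequence_entirely_undefined(self):
        rr = behavior.compute_reward_rate([1, 0, 1])
        assert not rr.valid.any()
        assert np.isnan(rr.values).all()

    @given(st.lists(st.booleans(), min_size=6, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_values_on_grid_and_shift_equivariance(self, outcomes):
        rr = behavior.compute_reward_rate(outcomes)
        grid = {0.0, 0.2, 0.4, 0.6, 0.8, 1.0}
        assert all(round(v, 10) in grid for v in rr.values[rr.valid])
        # Prepending one trial shifts the defined series by one trial.
        shifted = behavior.compute_reward_rate([False] + outcomes)
        np.testing.assert_allclose(shifted.values[6:], rr.values[5:], equal_nan=True)


class TestChoiceRegression:
    def test_recovers_known_policy_weights(self, task_config):
        truth = PolicyParams(
            beta_reward=(1.2, 0.6, 0.3, 0.1), beta_noreward=(-0.8, -0.3, 0.0, 0.1), beta0=0.2
        )
        log = task_sim.run_session(task_config, truth, 8000, seed=31)
        fit = behavior.fit_choice_regression(log, n_past=4)
        assert not fit.separation_flag
        for est, se, true in zip(
            np.concatenate([fit.beta_reward, fit.beta_noreward, [fit.beta0]]),
            np.concatenate([fit.se_reward, fit.se_noreward, [fit.se_beta0]]),
            np.concatenate([truth.beta_reward, truth.beta_noreward, [truth.beta0]]),
        ):
            assert abs(est - true) < 3 * se

    def test_random_agent_yields_null_coefficients(self, task_config):
        null = PolicyParams(beta_reward=(0.0,) * 4, beta_noreward=(0.0,) * 4, beta0=0.0)
        log = task_sim.run_session(task_config, null, 6000, seed=13)
        fit = behavior.fit_choice_regression(log, n_past=4)
        est = np.concatenate([fit.beta_reward, fit.beta_noreward, [fit.beta0]])
        se = np.concatenate([fit.se_reward, fit.se_noreward, [fit.se_beta0]])
        assert np.all(np.abs(est) < 3 * se)

    def test_fit_beats_brute_force_likelihood_grid(self):
        # 12 hand-built trials, one-lag model: the MLE must dominate a
        # 51-point grid over each coefficient around it.
        pattern = [
            ("push", True), ("push", True), ("pull", False), ("push", False),
            ("pull", True), ("pull", True), ("push", False), ("pull", False),
            ("push", True), ("pull", True), ("push", False), ("pull", True),
        ]
        trials = [
            make_trial(i, choice=c, rewarded=r, t0=2.0 * i) for i, (c, r) in enumerate(pattern)
        ]
        log = task_sim.SessionLog(trials=trials, config=task_sim.TaskConfig())
        fit = behavior.fit_choice_regression(log, n_past=1)
        X, y = behavior.design_matrix(log.to_frame(), 1)

        def loglik(b):
            logit = X @ b
            return float(np.sum(y * logit - np.log1p(np.exp(logit))))

        b_hat = np.array([fit.beta_reward[0], fit.beta_noreward[0], fit.beta0])
        best = loglik(b_hat)
        for k in range(3):
            for val in np.linspace(b_hat[k] - 2.0, b_hat[k] + 2.0, 51):
                b = b_hat.copy()
                b[k] = val
                assert loglik(b) <= best + 1e-8

    def test_label_exchange_flips_only_intercept(self, task_config):
        truth = PolicyParams(beta_reward=(1.0, 0.4), beta_noreward=(-0.6, 0.0), beta0=0.3)
        log = task_sim.run_session(task_config, truth, 3000, seed=7)
        df = log.to_frame()
        swapped = df.copy()
        swapped["choice"] = np.where(df["choice"] == "push", "pull", "push")
        a = behavior.fit_choice_regression(df, n_past=2)
        b = behavior.fit_choice_regression(swapped, n_past=2)
        np.testing.assert_allclose(a.beta_reward, b.beta_reward, atol=1e-6)
        np.testing.assert_allclose(a.beta_noreward, b.beta_noreward, atol=1e-6)
        assert a.beta0 == pytest.approx(-b.beta0, abs=1e-6)

    def test_single_action_session_rejected(self, task_config):
        trials = [make_trial(i, choice="push", rewarded=True, t0=2.0 * i) for i in range(30)]
        log = task_sim.SessionLog(trials=trials, config=task_config)
        with pytest.raises(ValueError):
            behavior.fit_choice_regression(log, n_past=2)


class TestSwitchProbability:
    def _session(self, policy, n=400, seed=5):
        cfg = task_sim.TaskConfig()
        params = task_sim.stay_biased_params()
        return task_sim.run_session(cfg, params, n, seed=seed, policy=policy)

    def test_perseverating_agent_never_switches(self):
        log = self._session(lambda h, p, rng: "push" if not h else h[-1].choice)
        table = behavior.switch_probability_by_reward_rate(log)
        filled = table.dropna(subset=["p_switch"])
        assert (filled["p_switch"] == 0).all()

    def test_strict_lose_switch_agent(self):
        def policy(history, params, rng):
            if not history:
                return "push"
            last = history[-1]
            if last.rewarded:
                return last.choice
            return "pull" if last.choice == "push" else "push"

        table = behavior.switch_probability_by_reward_rate(self._session(policy))
        nr = table[(table["outcome"] == "nonrewarded") & (table["n_trials"] > 0)]
        rw = table[(table["outcome"] == "rewarded") & (table["n_trials"] > 0)]
        assert (nr["p_switch"] == 1.0).all()
        assert (rw["p_switch"] == 0.0).all()

    def test_empty_cells_reported_missing(self, stay_session):
        table = behavior.switch_probability_by_reward_rate(stay_session)
        empty = table[table["n_trials"] == 0]
        assert empty["p_switch"].isna().all()


class TestMovementOnset:
    def test_flat_trajectory_raises(self):
        with pytest.raises(NoMovementDetected):
            behavior.detect_movement_onset(np.zeros(500), (0, 200))

    def test_large_step_detected_at_its_first_sample(self):
        rng = np.random.default_rng(17)
        x = rng.normal(0.0, 1.0, 600)
        x[400:] += 10.0
        assert behavior.detect_movement_onset(x, (0, 300)) == 400

    def test_ramp_onset_within_three_samples_median(self):
        rng = np.random.default_rng(29)
        errors = []
        for _ in range(300):
            x = rng.normal(0.0, 1.0, 500)
            t0 = 300
            x[t0:] += 5.0 * np.arange(200)
            errors.append(behavior.detect_movement_onset(x, (0, 250)) - t0)
        assert abs(np.median(errors)) <= 3

    def test_false_alarm_rate_on_pure_noise_below_one_percent(self):
        rng = np.random.default_rng(41)
        n = 800
        alarms = 0
        for _ in range(n):
            x = rng.normal(0.0, 1.0, 500)
            try:
                behavior.detect_movement_onset(x, (0, 200))
                alarms += 1
            except NoMovementDetected:
                pass
        assert alarms / n <= 0.01

    def test_empty_hold_interval_rejected(self):
        with pytest.raises(ValueError):
            behavior.detect_movement_onset(np.zeros(10), (5, 5))
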