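"""Behavioral statistics: reward rate, past-outcome regression, switch curves, onset detection.

The reward rate is the proxy for reward expectation: the mean number of
rewards over the five trials preceding the current one (the current trial
is excluded), taking values on the grid {0, 0.2, ..., 1}. The logistic
regression quantifies how rewarded and unrewarded past choices steer the
current push/pull decision; positive reward weights express win-stay,
negative no-reward weights express lose-switch. Movement onset on the lever
trajectory is detected with a one-sided CUSUM against the hold-period
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from nsr.task_sim import PUSH, PolicyParams, SessionLog, signed_regressors


@dataclass
class RewardRateSeries:
    """Per-trial reward rate with an explicit validity mask.

    ``values[i]`` is the fraction of rewarded trials among trials
    ``i-window ... i-1``; trials without a full window are flagged invalid
    (NaN value) rather than extrapolated.
    """

    values: np.ndarray
    valid: np.ndarray
    window: int

    @property
    def valid_from(self) -> int | None:
        idx = np.flatnonzero(self.valid)
        return int(idx[0]) if idx.size else None


def compute_reward_rate(outcomes, window: int = 5) -> RewardRateSeries:
    """Trailing-window reward rate, excluding the current trial.

    Parameters
    ----------
    outcomes:
        Boolean sequence, one entry per trial (True = rewarded).
    window:
        Number of preceding trials to average over (default 5).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(outcomes, dtype=float)
    n = x.size
    values = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    if n >= window:
        csum = np.concatenate([[0.0], np.cumsum(x)])
        for i in range(window, n):
            values[i] = (csum[i] - csum[i - window]) / window
            valid[i] = True
    return RewardRateSeries(values=values, valid=valid, window=window)


@dataclass
class ChoiceRegressionFit:
    """Maximum-likelihood fit of the past-outcome logistic choice model."""

    beta_reward: np.ndarray
    beta_noreward: np.ndarray
    beta0: float
    se_reward: np.ndarray
    se_noreward: np.ndarray
    se_beta0: float
    p_reward: np.ndarray
    p_noreward: np.ndarray
    p_beta0: float
    n_trials_used: int
    n_past: int
    converged: bool
    separation_flag: bool = False

    def params_as_policy(self) -> PolicyParams:
        return PolicyParams(
            beta_reward=tuple(self.beta_reward),
            beta_noreward=tuple(self.beta_noreward),
            beta0=self.beta0,
        )


def design_matrix(session: SessionLog | pd.DataFrame, n_past: int):
    """Signed-regressor design matrix and push-indicator response.

    Rows are trials ``n_past ... n-1`` (earlier trials lack a full history
    and are excluded). Columns: reward lags 1..n_past, no-reward lags
    1..n_past, constant.
    """
    if isinstance(session, SessionLog):
        df = session.to_frame()
    else:
        df = session
    n = len(df)
    push = (df["choice"].to_numpy() == PUSH)
    rewarded = df["rewarded"].to_numpy().astype(bool)
    sign = np.where(push, 1.0, -1.0)
    rew = np.where(rewarded, sign, 0.0)
    norew = np.where(~rewarded, sign, 0.0)
    rows = n - n_past
    X = np.empty((rows, 2 * n_past + 1))
    for j in range(n_past):  # lag j+1: trial i-1-j for i = n_past..n-1
        X[:, j] = rew[n_past - 1 - j : n - 1 - j]
        X[:, n_past + j] = norew[n_past - 1 - j : n - 1 - j]
    X[:, -1] = 1.0
    y = push[n_past:].astype(float)
    return X, y


def fit_choice_regression(session: SessionLog | pd.DataFrame, n_past: int = 8) -> ChoiceRegressionFit:
    """Fit the push-choice logistic regression on signed past-outcome regressors.

    Raises ``ValueError`` when the session is too short or only one action
    occurs. Perfect separation is reported via ``separation_flag`` instead
    of silently diverging.
    """
    X, y = design_matrix(session, n_past)
    if len(y) < n_past + 1:
        raise ValueError("session must contain more than n_past usable trials")
    if y.min() == y.max():
        raise ValueError("both push and pull choices must be represented")
    separation = False
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
        params = np.asarray(res.params)
        bse = np.asarray(res.bse)
        pvals = np.asarray(res.pvalues)
        # Huge coefficients with huge/undefined SEs indicate quasi-separation.
        if not np.all(np.isfinite(bse)) or np.any(np.abs(params) > 20):
            separation = True
    except (PerfectSeparationError, np.linalg.LinAlgError):
        separation = True
        converged = False
        params = np.full(2 * n_past + 1, np.nan)
        bse = np.full(2 * n_past + 1, np.nan)
        pvals = np.full(2 * n_past + 1, np.nan)
    return ChoiceRegressionFit(
        beta_reward=params[:n_past],
        beta_noreward=params[n_past : 2 * n_past],
        beta0=float(params[-1]),
        se_reward=bse[:n_past],
        se_noreward=bse[n_past : 2 * n_past],
        se_beta0=float(bse[-1]),
        p_reward=pvals[:n_past],
        p_noreward=pvals[n_past : 2 * n_past],
        p_beta0=float(pvals[-1]),
        n_trials_used=len(y),
        n_past=n_past,
        converged=converged,
        separation_flag=separation,
    )


REWARD_RATE_LEVELS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


def switch_probability_by_reward_rate(session: SessionLog, window: int = 5) -> pd.DataFrame:
    """P(switch on next trial) by reward-rate level and current outcome.

    Returns one row per (reward-rate level, outcome) cell with the switch
    probability and the trial count; empty cells carry NaN probability and
    count 0 rather than an implicit zero.
    """
    df = session.to_frame()
    rr = compute_reward_rate(df["rewarded"].to_numpy(), window=window)
    choices = df["choice"].to_numpy()
    rewarded = df["rewarded"].to_numpy().astype(bool)
    rows = []
    for level in REWARD_RATE_LEVELS:
        for outcome in (True, False):
            num = 0
            den = 0
            for i in range(len(df) - 1):
                if not rr.valid[i] or not np.isclose(rr.values[i], level):
                    continue
                if rewarded[i] != outcome:
                    continue
                den += 1
                num += int(choices[i + 1] != choices[i])
            rows.append(
                {
                    "reward_rate": level,
                    "outcome": "rewarded" if outcome else "nonrewarded",
                    "p_switch": num / den if den else np.nan,
                    "n_trials": den,
                }
            )
    return pd.DataFrame(rows)


class NoMovementDetected(RuntimeError):
    """Raised when the CUSUM bound is never crossed after the Go cue."""


def detect_movement_onset(
    trajectory,
    hold_interval: tuple[int, int],
    go_index: int | None = None,
    n_sigma: float = 3.0,
    reference: float = 2.0,
) -> int:
    """CUSUM movement-onset detection on a lever-position trace.

    Baseline mean and SD come from ``hold_interval`` (half-open sample
    range). Two one-sided CUSUM recursions with reference value
    ``reference * sigma``, ``S±_t = max(0, S±_{t-1} ± (x_t - mu) - k)``,
    accumulate sustained signed departures from the hold baseline (the
    lever may move in either direction); onset is the first sample at or
    after ``go_index`` (default: end of the hold interval) where either
    statistic exceeds ``n_sigma * sigma``. The reference value keeps the
    noise-driven walk strongly mean-reverting, so pure hold noise rarely
    reaches the bound, while genuine lever excursions (tens of baseline
    SDs) cross it within a sample or two.
    """
    x = np.asarray(trajectory, dtype=float)
    lo, hi = hold_interval
    if hi <= lo:
        raise ValueError("hold_interval must be non-empty")
    base = x[lo:hi]
    mu = base.mean()
    sigma = base.std(ddof=0)
    start = hi if go_index is None else go_index
    if sigma == 0.0:
        # Noiseless baseline: any departure from the hold mean is movement.
        dev = np.flatnonzero(x[start:] != mu)
        if dev.size == 0:
            raise NoMovementDetected("trajectory never leaves the hold baseline")
        return start + int(dev[0])
    s_up = 0.0
    s_dn = 0.0
    bound = n_sigma * sigma
    k = reference * sigma
    for t in range(start, x.size):
        dev = x[t] - mu
        s_up = max(0.0, s_up + dev - k)
        s_dn = max(0.0, s_dn - dev - k)
        if s_up > bound or s_dn > bound:
            return t
    raise NoMovementDetected("CUSUM bound never crossed after the Go cue")


def summarize_fits(fits: list[ChoiceRegressionFit]) -> pd.DataFrame:
    """Across-session mean ± SD of regression coefficients, one row per term."""
    if not fits:
        raise ValueError("need at least one fit")
    n_past = fits[0].n_past
    rows = []
    for j in range(n_past):
        br = [f.beta_reward[j] for f in fits]
        bn = [f.beta_noreward[j] for f in fits]
        rows.append({"term": f"reward_lag{j + 1}", "mean": np.mean(br), "sd": np.std(br, ddof=1) if len(br) > 1 else np.nan})
        rows.append({"term": f"noreward_lag{j + 1}", "mean": np.mean(bn), "sd": np.std(bn, ddof=1) if len(bn) > 1 else np.nan})
    b0 = [f.beta0 for f in fits]
    rows.append({"term": "intercept", "mean": np.mean(b0), "sd": np.std(b0, ddof=1) if len(b0) > 1 else np.nan})
    return pd.DataFrame(rows)
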