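"""Simulator of the probabilistic push/pull block-reversal choice task.

A session is a sequence of trials. On each trial the agent pushes or pulls
a lever; the action matching the current block is "correct" and rewarded
with high probability (default 0.70), the other with low probability
(default 0.10). The block reverses once the agent has accumulated at least
``switch_min_correct`` correct choices within the block *and* exceeded
``switch_rate_threshold`` correct over the last ``switch_window`` trials.

Choice policies are logistic: the log-odds of pushing is a weighted sum of
signed past-outcome regressors (win-stay / lose-switch structure) plus an
intercept. Sessions generated with known policy weights serve as ground
truth for the behavioral regression in :mod:`nsr.behavior`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PUSH = "push"
PULL = "pull"
ACTIONS = (PUSH, PULL)

#: Delay from outcome-tone onset to reward delivery (s).
REWARD_DELAY_S = 0.3


@dataclass(frozen=True)
class TaskConfig:
    """Task rules and event-timing parameters.

    Parameters
    ----------
    p_reward_correct, p_reward_incorrect:
        Reward probability for the block-congruent and -incongruent action.
    switch_min_correct:
        Minimum correct choices accumulated in a block before reversal.
    switch_rate_threshold:
        Correct-rate bound over the last ``switch_window`` trials; the
        comparison is strict (rate must exceed the threshold).
    hold_duration_s, hold_jitter_s:
        Center-hold duration before the Go cue (mean ± uniform jitter).
    outcome_tone_delay_s:
        Delay from outcome-tone onset to reward delivery for rewarded trials.
    """

    p_reward_correct: float = 0.70
    p_reward_incorrect: float = 0.10
    switch_min_correct: int = 30
    switch_rate_threshold: float = 0.79
    switch_window: int = 10
    hold_duration_s: float = 0.4
    hold_jitter_s: float = 0.1
    outcome_tone_delay_s: float = REWARD_DELAY_S
    reaction_median_s: float = 0.30
    reaction_sigma: float = 0.25
    movement_median_s: float = 0.25
    movement_sigma: float = 0.20
    intertrial_s: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_reward_correct", "p_reward_incorrect", "switch_rate_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.switch_min_correct < 1:
            raise ValueError("switch_min_correct must be >= 1")
        if self.switch_window < 1:
            raise ValueError("switch_window must be >= 1")


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial with its event timestamps (seconds from session start)."""

    index: int
    block: str
    choice: str
    correct: bool
    rewarded: bool
    go_time: float
    movement_onset_time: float
    outcome_tone_time: float
    reward_time: float | None = None

    def __post_init__(self) -> None:
        if self.block not in ACTIONS or self.choice not in ACTIONS:
            raise ValueError("block and choice must be 'push' or 'pull'")
        if not self.outcome_tone_time > self.movement_onset_time > self.go_time:
            raise ValueError("event times must satisfy tone > movement onset > go")


@dataclass(frozen=True)
class PolicyParams:
    """Weights of the logistic choice policy.

    ``beta_reward[j]`` weights the signed regressor of the rewarded trial
    ``j+1`` back; positive values mean "stay after reward". ``beta_noreward``
    is the analogue for unrewarded trials; negative values mean "switch
    after no reward". ``beta0`` is a push bias.
    """

    beta_reward: tuple[float, ...]
    beta_noreward: tuple[float, ...]
    beta0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta_reward", tuple(float(b) for b in self.beta_reward))
        object.__setattr__(self, "beta_noreward", tuple(float(b) for b in self.beta_noreward))
        if len(self.beta_reward) != len(self.beta_noreward):
            raise ValueError("beta_reward and beta_noreward must have equal length")
        if self.n_past < 1:
            raise ValueError("n_past must be >= 1")

    @property
    def n_past(self) -> int:
        return len(self.beta_reward)


def stay_biased_params(n_past: int = 8) -> PolicyParams:
    """A win-stay / mild lose-switch agent that reliably completes blocks.

    Recency-weighted positive reward weights make the agent repeat rewarded
    choices; the small negative no-reward weight at lag 1 produces occasional
    exploratory switches, so both actions are sampled and reversals are
    discovered quickly.
    """
    beta_r = tuple(3.0 * 0.5**j for j in range(n_past))
    beta_n = tuple([-0.8] + [0.0] * (n_past - 1))
    return PolicyParams(beta_reward=beta_r, beta_noreward=beta_n, beta0=0.0)


def signed_regressors(history: list[TrialRecord] | pd.DataFrame, i: int, n_past: int):
    """Signed past-outcome regressors for trial ``i``.

    ``reward[j]`` is +1 if trial ``i-1-j`` was rewarded and a push, -1 if
    rewarded and a pull, 0 if unrewarded or absent; ``noreward[j]`` is the
    analogue for unrewarded trials. Missing history (early trials) pads
    with zeros.
    """
    if isinstance(history, pd.DataFrame):
        choices = history["choice"].tolist()
        rewards = history["rewarded"].tolist()

        def record(k):
            return choices[k], rewards[k]

        n = len(choices)
    else:

        def record(k):
            t = history[k]
            return t.choice, t.rewarded

        n = len(history)
    reward = np.zeros(n_past)
    noreward = np.zeros(n_past)
    for j in range(n_past):
        k = i - 1 - j
        if k < 0 or k >= n:
            continue
        choice, rewarded = record(k)
        sign = 1.0 if choice == PUSH else -1.0
        if rewarded:
            reward[j] = sign
        else:
            noreward[j] = sign
    return reward, noreward


def push_probability(history: list[TrialRecord], params: PolicyParams) -> float:
    """Probability of choosing push on the next trial under the logistic policy."""
    i = len(history)
    reward, noreward = signed_regressors(history, i, params.n_past)
    logit = (
        float(np.dot(params.beta_reward, reward))
        + float(np.dot(params.beta_noreward, noreward))
        + params.beta0
    )
    return 1.0 / (1.0 + np.exp(-logit))


def logistic_policy_choice(
    history: list[TrialRecord], params: PolicyParams, rng: np.random.Generator
) -> str:
    """Sample the next action from the logistic policy given trial history."""
    p_push = push_probability(history, params)
    return PUSH if rng.random() < p_push else PULL


def draw_outcome(
    choice: str, block: str, config: TaskConfig, rng: np.random.Generator
) -> bool:
    """Draw the trial outcome: rewarded with the block-dependent probability."""
    if choice not in ACTIONS or block not in ACTIONS:
        raise ValueError("choice and block must be 'push' or 'pull'")
    p = config.p_reward_correct if choice == block else config.p_reward_incorrect
    return bool(rng.random() < p)


def should_switch_block(trials_in_block: list[TrialRecord], config: TaskConfig) -> bool:
    """Block-reversal predicate.

    True iff the block holds at least ``switch_min_correct`` correct choices
    and the correct fraction over the last ``switch_window`` trials strictly
    exceeds ``switch_rate_threshold``.
    """
    if not trials_in_block:
        return False
    n_correct = sum(t.correct for t in trials_in_block)
    if n_correct < config.switch_min_correct:
        return False
    recent = trials_in_block[-config.switch_window :]
    if len(recent) < config.switch_window:
        return False
    rate = sum(t.correct for t in recent) / len(recent)
    return rate > config.switch_rate_threshold


@dataclass
class SessionLog:
    """An ordered session of trials with its block-reversal bookkeeping.

    ``block_boundaries`` lists the indices of the first trial of each new
    block (reversals); the completed block preceding each boundary satisfies
    the switch rule by construction.
    """

    trials: list[TrialRecord]
    config: TaskConfig
    params: PolicyParams | None = None
    block_boundaries: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def outcomes(self) -> np.ndarray:
        return np.array([t.rewarded for t in self.trials], dtype=bool)

    @property
    def choices(self) -> np.ndarray:
        return np.array([t.choice for t in self.trials])

    def to_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(t) for t in self.trials]
        df = pd.DataFrame(rows)
        df["reward_time"] = df["reward_time"].astype(float)  # None -> NaN
        return df

    def completed_blocks(self) -> list[list[TrialRecord]]:
        """Trials of each completed (reversed-out-of) block, in order."""
        blocks = []
        start = 0
        for b in self.block_boundaries:
            blocks.append(self.trials[start:b])
            start = b
        return blocks

    def save(self, out_dir: str | Path) -> tuple[Path, Path]:
        """Write the trial table (CSV) and a config/params JSON sidecar."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        csv_path = out_dir / "session.csv"
        df = self.to_frame()
        for col in ("go_time", "movement_onset_time", "outcome_tone_time", "reward_time"):
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{v:.6f}")
        df.to_csv(csv_path, index=False)
        meta = {
            "config": dataclasses.asdict(self.config),
            "params": dataclasses.asdict(self.params) if self.params else None,
            "block_boundaries": list(self.block_boundaries),
        }
        json_path = out_dir / "session.json"
        json_path.write_text(json.dumps(meta, indent=2))
        return csv_path, json_path

    @classmethod
    def load(cls, out_dir: str | Path) -> "SessionLog":
        out_dir = Path(out_dir)
        df = pd.read_csv(out_dir / "session.csv")
        meta = json.loads((out_dir / "session.json").read_text())
        config = TaskConfig(**meta["config"])
        params = None
        if meta.get("params"):
            p = meta["params"]
            params = PolicyParams(
                beta_reward=tuple(p["beta_reward"]),
                beta_noreward=tuple(p["beta_noreward"]),
                beta0=p["beta0"],
            )
        trials = []
        for _, row in df.iterrows():
            rt = row["reward_time"]
            trials.append(
                TrialRecord(
                    index=int(row["index"]),
                    block=row["block"],
                    choice=row["choice"],
                    correct=bool(row["correct"]),
                    rewarded=bool(row["rewarded"]),
                    go_time=float(row["go_time"]),
                    movement_onset_time=float(row["movement_onset_time"]),
                    outcome_tone_time=float(row["outcome_tone_time"]),
                    reward_time=None if pd.isna(rt) else float(rt),
                )
            )
        return cls(
            trials=trials,
            config=config,
            params=params,
            block_boundaries=list(meta["block_boundaries"]),
        )


def run_session(
    config: TaskConfig,
    params: PolicyParams,
    n_trials: int,
    seed: int,
    *,
    policy=None,
) -> SessionLog:
    """Simulate a session of ``n_trials`` trials, reproducible given ``seed``.

    ``policy`` may override the default logistic policy with any callable
    ``(history, params, rng) -> action``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    choose = policy if policy is not None else logistic_policy_choice
    trials: list[TrialRecord] = []
    boundaries: list[int] = []
    block = PUSH
    block_start = 0
    t = 0.0
    for i in range(n_trials):
        hold = config.hold_duration_s + rng.uniform(-config.hold_jitter_s, config.hold_jitter_s)
        go = t + hold
        reaction = float(rng.lognormal(np.log(config.reaction_median_s), config.reaction_sigma))
        onset = go + reaction
        move = float(rng.lognormal(np.log(config.movement_median_s), config.movement_sigma))
        tone = onset + move
        choice = choose(trials, params, rng)
        rewarded = draw_outcome(choice, block, config, rng)
        trials.append(
            TrialRecord(
                index=i,
                block=block,
                choice=choice,
                correct=choice == block,
                rewarded=rewarded,
                go_time=go,
                movement_onset_time=onset,
                outcome_tone_time=tone,
                reward_time=tone + config.outcome_tone_delay_s if rewarded else None,
            )
        )
        t = tone + config.outcome_tone_delay_s + config.intertrial_s
        if should_switch_block(trials[block_start:], config):
            block = PULL if block == PUSH else PUSH
            boundaries.append(i + 1)
            block_start = i + 1
    return SessionLog(trials=trials, config=config, params=params, block_boundaries=boundaries)


def run_until_blocks(
    config: TaskConfig,
    params: PolicyParams,
    n_blocks: int,
    seed: int,
    *,
    max_trials: int = 100_000,
) -> SessionLog:
    """Simulate until ``n_blocks`` block reversals have completed.

    The session is grown in chunks; raises if ``max_trials`` is reached
    first (an agent that cannot satisfy the switch rule).
    """
    n = 2_000
    while n <= max_trials:
        log = run_session(config, params, n, seed)
        if len(log.block_boundaries) >= n_blocks:
            idx = log.block_boundaries[n_blocks - 1]
            trimmed = SessionLog(
                trials=log.trials[:idx],
                config=config,
                params=params,
                block_boundaries=log.block_boundaries[:n_blocks],
            )
            return trimmed
        n *= 2
    raise RuntimeError(f"agent failed to complete {n_blocks} blocks within {max_trials} trials")
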