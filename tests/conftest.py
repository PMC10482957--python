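import numpy as np
import pytest

from nsr import task_sim


@pytest.fixture(scope="session")
def task_config():
    return task_sim.TaskConfig()


@pytest.fixture(scope="session")
def stay_params():
    return task_sim.stay_biased_params()


@pytest.fixture(scope="session")
def stay_session(task_config, stay_params):
    """A 2,000-trial session from the win-stay agent (dozens of reversals)."""
    return task_sim.run_session(task_config, stay_params, 2000, seed=11)


@pytest.fixture(scope="session")
def short_session(task_config, stay_params):
    """A 150-trial session for analyses that only need event structure."""
    return task_sim.run_session(task_config, stay_params, 150, seed=23)


def make_trial(index, block="push", choice="push", rewarded=True, t0=0.0):
    """Hand-built trial with consistent event times."""
    return task_sim.TrialRecord(
        index=index,
        block=block,
        choice=choice,
        correct=choice == block,
        rewarded=rewarded,
        go_time=t0 + 0.4,
        movement_onset_time=t0 + 0.7,
        outcome_tone_time=t0 + 1.0,
        reward_time=t0 + 1.3 if rewarded else None,
    )


def make_block(pattern, block="push"):
    """Trials from a correctness pattern: '+' correct, '-' incorrect."""
    other = "pull" if block == "push" else "push"
    return [
        make_trial(i, block=block, choice=block if c == "+" else other, rewarded=c == "+", t0=2.0 * i)
        for i, c in enumerate(pattern)
    ]
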