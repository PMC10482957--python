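"""Run configuration, validation and seed derivation.

A :class:`RunConfig` collects the tunable parameters of every pipeline
stage plus a single global seed; per-stage seeds are derived from it with
``numpy.random.SeedSequence`` so no stage reads ambient entropy. Configs
round-trip through YAML; unknown keys are rejected on load.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from nsr.task_sim import PolicyParams, TaskConfig, stay_biased_params

#: Fixed stage order; also the seed-derivation order.
STAGES = (
    "simulate",
    "synth_spikes",
    "synth_photometry",
    "synth_collision",
    "behavior",
    "photometry",
    "identify",
    "classify",
    "peth",
)


@dataclass
class SynthSection:
    n_units: int = 12
    baseline_hz: float = 5.0
    movement_gain_hz: float = 20.0
    outcome_gain_hz: float = 15.0
    movement_coupling: float = 1.0
    outcome_coupling: float = -0.8
    photometry_noise_sd: float = 0.3
    collision_n_control: int = 50
    collision_n_test: int = 50


@dataclass
class AnalysisSection:
    n_past: int = 8
    reward_rate_window: int = 5
    task_related_alpha: float = 0.05
    outcome_contrast_alpha: float = 0.01


@dataclass
class RunConfig:
    """Parameters of an end-to-end run."""

    task: TaskConfig = field(default_factory=TaskConfig)
    policy: PolicyParams = field(default_factory=stay_biased_params)
    synth: SynthSection = field(default_factory=SynthSection)
    analysis: AnalysisSection = field(default_factory=AnalysisSection)
    n_trials: int = 300
    seed: int = 0
    out_dir: str = "nsr_run"
    log_level: str = "INFO"

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        children = np.random.SeedSequence(self.seed).spawn(len(STAGES))
        return int(children[STAGES.index(stage)].generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)

        def build(tp, section):
            known = {f.name for f in dataclasses.fields(tp)}
            unknown = set(section) - known
            if unknown:
                raise ValueError(f"unknown keys in {tp.__name__}: {sorted(unknown)}")
            return tp(**section)

        kwargs = {}
        if "task" in data:
            kwargs["task"] = build(TaskConfig, data.pop("task"))
        if "policy" in data:
            p = data.pop("policy")
            unknown = set(p) - {"beta_reward", "beta_noreward", "beta0"}
            if unknown:
                raise ValueError(f"unknown keys in PolicyParams: {sorted(unknown)}")
            kwargs["policy"] = PolicyParams(
                beta_reward=tuple(p["beta_reward"]),
                beta_noreward=tuple(p["beta_noreward"]),
                beta0=p.get("beta0", 0.0),
            )
        if "synth" in data:
            kwargs["synth"] = build(SynthSection, data.pop("synth"))
        if "analysis" in data:
            kwargs["analysis"] = build(AnalysisSection, data.pop("analysis"))
        top_known = {"n_trials", "seed", "out_dir", "log_level"}
        unknown = set(data) - top_known
        if unknown:
            raise ValueError(f"unknown keys in RunConfig: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
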