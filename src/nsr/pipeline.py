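"""End-to-end orchestration: simulate → synthesize → analyze → summarize.

``run_pipeline`` executes every stage on synthetic data derived from one
global seed and writes a manifest (config, per-stage artifacts, SHA-256
hashes) that makes a run exactly repeatable: identical configs and seeds
yield identical manifests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from nsr import behavior, classify, optotag, peth, photometry, synth, task_sim
from nsr.config import RunConfig
from nsr.io import file_sha256, save_ensemble, save_photometry, save_spikes

log = logging.getLogger("nsr")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _unit_specs(cfg: RunConfig) -> list[synth.NeuronSpec]:
    """A small synthetic population with alternating reward-rate couplings."""
    s = cfg.synth
    specs = []
    for i in range(s.n_units):
        sign = 1.0 if i % 2 == 0 else -1.0
        specs.append(
            synth.NeuronSpec(
                baseline_hz=s.baseline_hz,
                event_kernels={
                    "movement": synth.EventKernel(
                        gain_hz=s.movement_gain_hz, coupling=sign * s.movement_coupling
                    ),
                    "outcome_reward": synth.EventKernel(
                        gain_hz=s.outcome_gain_hz, coupling=s.outcome_coupling
                    ),
                },
                label=f"unit{i:02d}",
            )
        )
    return specs


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to the out dir)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, list[str]] = {}
    current = "simulate"

    def record(stage: str, *paths: Path):
        artifacts.setdefault(stage, []).extend(str(p.relative_to(out)) for p in paths)

    try:
        # --- simulate
        session = task_sim.run_session(
            cfg.task, cfg.policy, cfg.n_trials, cfg.stage_seed("simulate")
        )
        record("simulate", *session.save(out / "session"))
        df = session.to_frame()

        # --- synth spikes
        current = "synth_spikes"
        specs = _unit_specs(cfg)
        seed0 = cfg.stage_seed("synth_spikes")
        spikes = {
            spec.label: synth.gen_spike_train(spec, session, seed=seed0 + i)
            for i, spec in enumerate(specs)
        }
        record(current, save_spikes(spikes, out / "spikes.csv"))

        # --- synth photometry
        current = "synth_photometry"
        pspec = synth.PhotometrySpec(
            amplitudes={"movement": 0.04, "outcome_reward": 0.05},
            couplings={"movement": 0.8, "outcome_reward": -0.5},
            noise_sd=cfg.synth.photometry_noise_sd,
        )
        trace = synth.gen_photometry(pspec, session, seed=cfg.stage_seed("synth_photometry"))
        record(current, save_photometry(trace, out / "photometry"))

        # --- synth collision ensembles
        current = "synth_collision"
        cseed = cfg.stage_seed("synth_collision")
        ens_proj = synth.gen_collision_ensemble(
            synth.CollisionSpec(antidromic=True),
            cfg.synth.collision_n_control,
            cfg.synth.collision_n_test,
            seed=cseed,
        )
        ens_ctrl = synth.gen_collision_ensemble(
            synth.CollisionSpec(antidromic=False),
            cfg.synth.collision_n_control,
            cfg.synth.collision_n_test,
            seed=cseed + 1,
        )
        record(
            current,
            save_ensemble(ens_proj, out / "ensemble_projecting"),
            save_ensemble(ens_ctrl, out / "ensemble_nonprojecting"),
        )

        # --- behavior analysis
        current = "behavior"
        rr = behavior.compute_reward_rate(df["rewarded"].to_numpy(), cfg.analysis.reward_rate_window)
        rr_path = out / "reward_rate.csv"
        pd.DataFrame({"trial": np.arange(len(df)), "reward_rate": rr.values}).to_csv(
            rr_path, index=False
        )
        fit = behavior.fit_choice_regression(session, n_past=cfg.analysis.n_past)
        fit_path = out / "choice_regression.json"
        fit_path.write_text(
            json.dumps(
                {
                    "beta_reward": list(fit.beta_reward),
                    "beta_noreward": list(fit.beta_noreward),
                    "beta0": fit.beta0,
                    "se_reward": list(fit.se_reward),
                    "se_noreward": list(fit.se_noreward),
                    "n_trials_used": fit.n_trials_used,
                    "converged": fit.converged,
                    "separation_flag": fit.separation_flag,
                },
                indent=2,
            )
        )
        switch_path = out / "switch_probability.csv"
        behavior.switch_probability_by_reward_rate(session).to_csv(switch_path, index=False)
        record(current, rr_path, fit_path, switch_path)

        # --- photometry analysis
        current = "photometry"
        norm = photometry.process_trace(trace)
        mv = df["movement_onset_time"].to_numpy(dtype=float)
        aligned, taxis, kept = photometry.align_to_events(norm, mv, window=(1.0, 1.0))
        vals = photometry.window_values(aligned, taxis, photometry.MOVEMENT_WINDOW_S)
        kept_idx = [int(np.argmin(np.abs(mv - k))) for k in kept]
        pv = pd.DataFrame(
            {
                "trial": kept_idx,
                "movement_window_dff_z": vals,
                "reward_rate": rr.values[kept_idx],
                "choice": df["choice"].to_numpy()[kept_idx],
            }
        )
        pv_path = out / "photometry_window_values.csv"
        pv.to_csv(pv_path, index=False)
        push = pv.loc[pv["choice"] == "push", "movement_window_dff_z"].to_numpy()
        pull = pv.loc[pv["choice"] == "pull", "movement_window_dff_z"].to_numpy()
        pref = peth.action_preference(push, pull) if push.size and pull.size else "none"
        corr = peth.reward_rate_correlation(
            pv["movement_window_dff_z"].to_numpy(), pv["reward_rate"].to_numpy()
        )
        summary_path = out / "photometry_summary.json"
        summary_path.write_text(
            json.dumps(
                {
                    "action_preference": pref,
                    "included": pref != "none",
                    "movement_r": corr.r,
                    "movement_p": corr.p,
                    "n_trials": corr.n_trials,
                },
                indent=2,
            )
        )
        record(current, pv_path, summary_path)

        # --- optogenetic identification
        current = "identify"
        rows = []
        for name, ens in [("projecting", ens_proj), ("nonprojecting", ens_ctrl)]:
            res = optotag.collision_test(ens)
            rows.append({"unit": name, **dataclasses.asdict(res)})
        id_path = out / "identification.csv"
        pd.DataFrame(rows).to_csv(id_path, index=False)
        record(current, id_path)

        # --- classification
        current = "classify"
        pop = synth.gen_unit_population(seed=cfg.stage_seed("classify"))
        labeled = classify.classify_units(pop, seed=cfg.stage_seed("classify"))
        cls_path = out / "unit_labels.csv"
        labeled.to_csv(cls_path, index=False)
        record(current, cls_path)

        # --- peri-event statistics
        current = "peth"
        unit_rows = []
        for label, times in spikes.items():
            stats_ = peth.compute_window_stats(times, df)
            related = peth.task_related_test(stats_, alpha=cfg.analysis.task_related_alpha)
            if stats_.baseline_sd_zero or not related["testable"]:
                continue
            choice = df["choice"].to_numpy()
            pref_u = peth.action_preference(
                stats_.movement[choice == "push"], stats_.movement[choice == "pull"]
            )
            try:
                corr_u = peth.reward_rate_correlation(stats_.z_movement, rr.values)
            except ValueError:
                continue
            unit_rows.append(
                {
                    "unit": label,
                    "task_related": related["task_related"],
                    "action_preference": pref_u,
                    "movement_r": corr_u.r,
                    "movement_p": corr_u.p,
                    "n_trials": corr_u.n_trials,
                }
            )
        units_df = pd.DataFrame(unit_rows)
        peth_path = out / "unit_correlations.csv"
        units_df.to_csv(peth_path, index=False)
        rvals = units_df.loc[units_df["task_related"], "movement_r"].to_numpy()
        pop_p = peth.population_r_test(rvals) if rvals.size >= 5 else None
        pop_path = out / "population_summary.json"
        pop_path.write_text(
            json.dumps(
                {
                    "n_units": int(len(units_df)),
                    "n_task_related": int(units_df["task_related"].sum()),
                    "population_r_p": pop_p,
                    "median_r": float(np.median(rvals)) if rvals.size else None,
                },
                indent=2,
            )
        )
        record(current, peth_path, pop_path)
    except Exception as e:  # noqa: BLE001 - stage name is part of the contract
        log.error("stage %s failed: %s", current, e)
        raise StageFailure(current, e) from e

    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "stages": {
            stage: [{"path": p, "sha256": file_sha256(out / p)} for p in paths]
            for stage, paths in artifacts.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
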