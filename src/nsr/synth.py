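"""Ground-truth generators for spikes, photometry and collision-test ensembles.

Every generator is a deterministic function of its spec and a seed. The
generators encode the structure the analyses are built to recover:

- spike trains are inhomogeneous Poisson with event-locked double-
  exponential rate kernels whose gain scales linearly with the trailing
  reward rate of the trial;
- photometry channels combine a bleaching baseline (exponential + linear),
  event-locked release transients (470 nm only), shared motion artifacts
  and channel noise;
- collision ensembles emulate antidromic physics: a stimulus-locked spike
  at a fixed conduction latency that disappears whenever a spontaneous
  spike of the same unit precedes the pulse within the conduction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nsr.behavior import compute_reward_rate
from nsr.optotag import StimTrialEnsemble
from nsr.photometry import PhotometryTrace
from nsr.task_sim import SessionLog


# ---------------------------------------------------------------------------
# Spike trains


@dataclass(frozen=True)
class EventKernel:
    """Event-locked rate kernel: double-exponential shape with peak ``gain_hz``.

    ``coupling`` is the fractional gain change per unit reward rate
    (gain × (1 + coupling × reward_rate)).
    """

    gain_hz: float
    rise_s: float = 0.02
    decay_s: float = 0.15
    coupling: float = 0.0


@dataclass
class NeuronSpec:
    """Generative spec of one unit's event-locked firing."""

    baseline_hz: float = 5.0
    event_kernels: dict[str, EventKernel] = field(default_factory=dict)
    outcome_selectivity: float = 1.0
    dead_time_s: float = 0.0
    label: str = ""


def _kernel_shape(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Double exponential normalized to unit peak; zero for t < 0."""
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay) - np.exp(-np.maximum(t, 0) / rise), 0.0)
    peak = k.max()
    return k / peak if peak > 0 else k


def _event_times(session: SessionLog | pd.DataFrame) -> dict[str, np.ndarray]:
    df = session.to_frame() if isinstance(session, SessionLog) else session
    rewarded = df["rewarded"].to_numpy(dtype=bool)
    tone = df["outcome_tone_time"].to_numpy(dtype=float)
    return {
        "go": df["go_time"].to_numpy(dtype=float),
        "movement": df["movement_onset_time"].to_numpy(dtype=float),
        "outcome_reward": tone[rewarded],
        "outcome_noreward": tone[~rewarded],
    }


def intensity_on_grid(
    spec: NeuronSpec, session: SessionLog | pd.DataFrame, dt: float = 0.001
) -> tuple[np.ndarray, np.ndarray]:
    """Firing intensity λ(t) on a uniform grid covering the session."""
    df = session.to_frame() if isinstance(session, SessionLog) else session
    rr = compute_reward_rate(df["rewarded"].to_numpy()).values
    rewarded = df["rewarded"].to_numpy(dtype=bool)
    t_end = float(df["outcome_tone_time"].iloc[-1]) + 2.0
    t = np.arange(0.0, t_end, dt)
    lam = np.full(t.size, spec.baseline_hz)
    ev = _event_times(df)
    event_trial_idx = {
        "go": np.arange(len(df)),
        "movement": np.arange(len(df)),
        "outcome_reward": np.flatnonzero(rewarded),
        "outcome_noreward": np.flatnonzero(~rewarded),
    }
    for name, kern in spec.event_kernels.items():
        if name not in ev:
            raise ValueError(f"unknown event {name!r}")
        gain = kern.gain_hz
        if name == "outcome_noreward" and spec.outcome_selectivity != 1.0:
            gain = gain / spec.outcome_selectivity
        span = np.arange(0.0, kern.decay_s * 6 + kern.rise_s, dt)
        shape = _kernel_shape(span, kern.rise_s, kern.decay_s)
        for time, trial in zip(ev[name], event_trial_idx[name]):
            trial_rr = rr[trial]
            scale = 1.0 + (kern.coupling * trial_rr if np.isfinite(trial_rr) else 0.0)
            i0 = int(round(time / dt))
            i1 = min(i0 + shape.size, lam.size)
            if i0 < lam.size:
                lam[i0:i1] += gain * scale * shape[: i1 - i0]
    return t, np.maximum(lam, 0.0)


def gen_spike_train(
    spec: NeuronSpec, session: SessionLog | pd.DataFrame, seed: int, dt: float = 0.001
) -> np.ndarray:
    """Sample an inhomogeneous Poisson spike train from the spec's intensity.

    Counts are drawn per grid bin (``dt`` default 1 ms) and placed uniformly
    within the bin; an optional absolute dead time enforces sub-Poisson
    regularity for tonically regular cell types.
    """
    rng = np.random.default_rng(seed)
    t, lam = intensity_on_grid(spec, session, dt=dt)
    counts = rng.poisson(lam * dt)
    idx = np.repeat(np.arange(t.size), counts)
    spikes = np.sort(t[idx] + rng.uniform(0.0, dt, idx.size))
    if spec.dead_time_s > 0 and spikes.size:
        kept = [spikes[0]]
        for s in spikes[1:]:
            if s - kept[-1] >= spec.dead_time_s:
                kept.append(s)
        spikes = np.asarray(kept)
    return spikes


# ---------------------------------------------------------------------------
# Photometry


@dataclass
class PhotometrySpec:
    """Generative spec of a dual-channel dLight recording."""

    f0: float = 100.0
    bleach_a: float = 30.0
    bleach_tau_s: float = 600.0
    bleach_b: float = -0.002
    transient_rise_s: float = 0.05
    transient_decay_s: float = 0.4
    amplitudes: dict[str, float] = field(default_factory=dict)  # peak ΔF/F (fractional)
    couplings: dict[str, float] = field(default_factory=dict)  # per unit reward rate
    noise_sd: float = 0.3
    iso_gain: float = 0.8
    artifact_sd: float = 0.0
    artifact_fraction: float = 1.0
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if self.f0 <= 0 or self.bleach_tau_s <= 0:
            raise ValueError("f0 and bleach_tau_s must be positive")


def gen_photometry(spec: PhotometrySpec, session: SessionLog | pd.DataFrame, seed: int) -> PhotometryTrace:
    """Generate a paired 470/405 recording covering the session.

    The 470 channel carries the bleaching baseline, event-locked release
    transients and noise; the 405 channel carries the scaled baseline, a
    fraction of the shared motion artifact and independent noise, but no
    transients. Transient amplitudes are specified as peak ΔF/F — the
    fractional change over the local baseline fluorescence ``f0 +
    bleach(t)`` — and scale with 1 + coupling × reward rate of the trial.
    """
    rng = np.random.default_rng(seed)
    df = session.to_frame() if isinstance(session, SessionLog) else session
    rr = compute_reward_rate(df["rewarded"].to_numpy()).values
    rewarded = df["rewarded"].to_numpy(dtype=bool)
    t_end = float(df["outcome_tone_time"].iloc[-1]) + 2.0
    t = np.arange(0.0, t_end, 1.0 / spec.fs)
    bleach = spec.bleach_a * np.exp(-t / spec.bleach_tau_s) + spec.bleach_b * t
    transients = np.zeros(t.size)
    ev = _event_times(df)
    trial_idx = {
        "go": np.arange(len(df)),
        "movement": np.arange(len(df)),
        "outcome_reward": np.flatnonzero(rewarded),
        "outcome_noreward": np.flatnonzero(~rewarded),
    }
    span = np.arange(0.0, spec.transient_decay_s * 6 + spec.transient_rise_s, 1.0 / spec.fs)
    shape = _kernel_shape(span, spec.transient_rise_s, spec.transient_decay_s)
    for name, amp in spec.amplitudes.items():
        coupling = spec.couplings.get(name, 0.0)
        for time, trial in zip(ev[name], trial_idx[name]):
            trial_rr = rr[trial]
            scale = 1.0 + (coupling * trial_rr if np.isfinite(trial_rr) else 0.0)
            i0 = int(round(time * spec.fs))
            i1 = min(i0 + shape.size, transients.size)
            if i0 < transients.size:
                transients[i0:i1] += amp * scale * shape[: i1 - i0]
    if spec.artifact_sd > 0:
        # Slow shared artifact: smoothed random walk.
        steps = rng.normal(0.0, 1.0, t.size)
        walk = np.cumsum(steps)
        walk -= np.linspace(walk[0], walk[-1], t.size)
        artifact = spec.artifact_sd * walk / max(walk.std(ddof=0), 1e-12)
    else:
        artifact = np.zeros(t.size)
    baseline = spec.f0 + bleach
    sig = baseline * (1.0 + transients) + artifact
    iso = spec.iso_gain * (spec.f0 + bleach) + spec.artifact_fraction * artifact
    if spec.noise_sd > 0:
        sig = sig + rng.normal(0.0, spec.noise_sd, t.size)
        iso = iso + rng.normal(0.0, spec.noise_sd, t.size)
    return PhotometryTrace(signal_470=sig, isosbestic_405=iso, fs_acquired=spec.fs)


# ---------------------------------------------------------------------------
# Collision ensembles


@dataclass
class CollisionSpec:
    """Generative spec of a collision-test recording for one candidate unit."""

    conduction_latency_ms: float = 12.0
    latency_jitter_ms: float = 0.1
    spike_amplitude: float = 80.0
    noise_sd: float = 4.0
    spontaneous_rate_hz: float = 5.0
    antidromic: bool = True
    collision_failure_p: float = 0.0  # probability the collision fails to delete the spike
    fs: float = 20000.0
    pre_ms: float = 30.0
    post_ms: float = 30.0
    channel_gains: tuple[float, ...] = (1.0, 0.6, 0.35, 0.15)

    def __post_init__(self) -> None:
        if self.conduction_latency_ms <= 0 or self.latency_jitter_ms < 0:
            raise ValueError("latency must be positive and jitter non-negative")


def spike_waveform(fs: float, amplitude: float = 1.0) -> np.ndarray:
    """Biphasic extracellular spike template (~1 ms, negative-dominant)."""
    t = np.arange(0.0, 0.0012, 1.0 / fs)
    w = -np.exp(-((t - 0.0003) ** 2) / (2 * 0.0001**2)) + 0.35 * np.exp(
        -((t - 0.0007) ** 2) / (2 * 0.00018**2)
    )
    return amplitude * w


def _add_spike(traces: np.ndarray, trial: int, sample: int, template: np.ndarray, gains) -> None:
    n = traces.shape[2]
    i1 = min(sample + template.size, n)
    if sample >= n or i1 <= max(sample, 0):
        return
    i0 = max(sample, 0)
    seg = template[i0 - sample : i1 - sample]
    for ch, g in enumerate(gains):
        traces[trial, ch, i0:i1] += g * seg


def gen_collision_ensemble(
    spec: CollisionSpec, n_control: int, n_test: int, seed: int
) -> StimTrialEnsemble:
    """Generate control and collision-triggered stimulus-trial snippets.

    Control snippets (no spontaneous spike near the stimulus) contain the
    antidromic spike at the conduction latency ± jitter when the unit is a
    projection neuron. Test snippets are triggered by a spontaneous spike
    just before the pulse, so the antidromic spike is deleted (up to the
    configured collision-failure probability). Non-projecting units
    (``antidromic=False``) spike independently of the stimulus in both
    conditions.
    """
    if n_control < 1 or n_test < 1:
        raise ValueError("trial counts must be >= 1")
    rng = np.random.default_rng(seed)
    fs = spec.fs
    n_pre = int(round(spec.pre_ms * fs / 1000.0))
    n_post = int(round(spec.post_ms * fs / 1000.0))
    n_samp = n_pre + n_post
    n_ch = len(spec.channel_gains)
    template = spike_waveform(fs, spec.spike_amplitude)
    snippet_s = n_samp / fs

    def background(traces, trial, exclude_ms: tuple[float, float] | None):
        """Spontaneous spikes at the unit's ongoing rate, avoiding ``exclude_ms``."""
        n_spont = rng.poisson(spec.spontaneous_rate_hz * snippet_s)
        for _ in range(n_spont):
            t_ms = rng.uniform(0.0, snippet_s * 1000.0) - spec.pre_ms
            if exclude_ms is not None and exclude_ms[0] <= t_ms <= exclude_ms[1]:
                continue
            _add_spike(traces, trial, n_pre + int(round(t_ms * fs / 1000.0)), template, spec.channel_gains)

    control = rng.normal(0.0, spec.noise_sd, (n_control, n_ch, n_samp))
    test = rng.normal(0.0, spec.noise_sd, (n_test, n_ch, n_samp))
    guard = (-spec.conduction_latency_ms - 2.0, spec.conduction_latency_ms + 2.0)
    for i in range(n_control):
        # Control definition: no spontaneous spike within the conduction time
        # before the pulse; keep the post-stimulus window clean of background.
        background(control, i, guard)
        if spec.antidromic:
            lat = spec.conduction_latency_ms + rng.normal(0.0, spec.latency_jitter_ms)
            _add_spike(control, i, n_pre + int(round(lat * fs / 1000.0)), template, spec.channel_gains)
    trigger_ms = -3.0  # spontaneous trigger spike peak, ms before the pulse
    for i in range(n_test):
        background(test, i, guard)
        _add_spike(test, i, n_pre + int(round(trigger_ms * fs / 1000.0)), template, spec.channel_gains)
        if spec.antidromic and rng.random() < spec.collision_failure_p:
            lat = spec.conduction_latency_ms + rng.normal(0.0, spec.latency_jitter_ms)
            _add_spike(test, i, n_pre + int(round(lat * fs / 1000.0)), template, spec.channel_gains)
    return StimTrialEnsemble(control_traces=control, test_traces=test, fs=fs, stim_sample=n_pre)


# ---------------------------------------------------------------------------
# Unit feature populations


#: Class-conditional feature distributions (mean, SD) for striatal types:
#: ongoing rate (Hz), peak-to-valley width (µs), CV of ISI. Values follow
#: the physiology the classifier exploits: SPNs wide and slow, TANs tonic
#: and regular, FSIs narrow and fast.
STRIATAL_CLASS_STATS = {
    "SPN": {"rate": (1.8, 0.6), "width": (640.0, 45.0), "cv": (1.35, 0.15)},
    "TAN": {"rate": (5.5, 0.9), "width": (490.0, 40.0), "cv": (0.65, 0.08)},
    "FSI": {"rate": (16.0, 3.5), "width": (210.0, 25.0), "cv": (1.0, 0.12)},
}

#: Default class mix (SPN, TAN, FSI) matching reported striatal proportions.
STRIATAL_CLASS_MIX = (0.36, 0.61, 0.03)


def gen_unit_population(
    n_units: int = 300,
    mix: tuple[float, float, float] = STRIATAL_CLASS_MIX,
    spread: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic striatal unit-feature table with ground-truth class labels.

    Features are Gaussian per class (rates truncated at a small positive
    floor); ``spread`` scales all class SDs to widen or sharpen separation.
    """
    rng = np.random.default_rng(seed)
    classes = list(STRIATAL_CLASS_STATS)
    counts = np.floor(np.asarray(mix) * n_units).astype(int)
    counts[1] += n_units - counts.sum()  # remainder to the largest class
    rows = []
    for cls, n in zip(classes, counts):
        st = STRIATAL_CLASS_STATS[cls]
        rate = np.maximum(rng.normal(st["rate"][0], st["rate"][1] * spread, n), 0.05)
        width = np.maximum(rng.normal(st["width"][0], st["width"][1] * spread, n), 50.0)
        cv = np.maximum(rng.normal(st["cv"][0], st["cv"][1] * spread, n), 0.05)
        for r, w, c in zip(rate, width, cv):
            rows.append(
                {
                    "ongoing_rate": r,
                    "spike_duration_us": w,
                    "cv_isi": c,
                    "region": "DMS",
                    "true_label": cls,
                }
            )
    df = pd.DataFrame(rows)
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
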