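"""Optogenetic unit identification.

Two routes prove that a recorded unit is the cell type of interest:

*Antidromic collision test.* Light pulses over the axon terminals evoke an
antidromic spike that propagates back to the soma at a fixed conduction
latency. If a spontaneous spike of the same unit fires just before the
pulse, the two spikes collide on the axon and the antidromic spike
disappears. Comparing stimulus-aligned traces with (test) and without
(control) a preceding spontaneous spike therefore identifies projection
neurons: control spike probability must exceed 50%, test probability must
fall below half of control, the 2×2 spike/no-spike table must reject
independence (chi-square, p < 0.05), latency must be under 25 ms and jitter
(interquartile range of peak times) under 0.5 ms.

*Direct tagging.* Somatic/axonal opsin activation evokes spikes at short
latency (< 8 ms striatonigral, < 10 ms striatopallidal), low jitter
(< 1 ms), and a light-evoked waveform nearly identical to the spontaneous
one (4-channel Pearson r > 0.9 over ±0.125 ms around the peak).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

MAX_ANTIDROMIC_LATENCY_MS = 25.0
MAX_ANTIDROMIC_JITTER_MS = 0.5
DIRECT_LATENCY_LIMIT_MS = {"striatonigral": 8.0, "striatopallidal": 10.0}
DIRECT_JITTER_LIMIT_MS = 1.0
DIRECT_WAVEFORM_R_MIN = 0.9
WAVEFORM_HALF_WINDOW_MS = 0.125


@dataclass
class StimTrialEnsemble:
    """Stimulus-aligned snippets for one candidate unit.

    ``control_traces`` / ``test_traces`` have shape (n_trials, n_channels,
    n_samples); test trials are those where a spontaneous spike of the
    candidate cluster triggered the light pulse.
    """

    control_traces: np.ndarray
    test_traces: np.ndarray
    fs: float
    stim_sample: int

    def __post_init__(self) -> None:
        self.control_traces = np.asarray(self.control_traces, dtype=float)
        self.test_traces = np.asarray(self.test_traces, dtype=float)
        if self.control_traces.ndim != 3 or self.test_traces.ndim != 3:
            raise ValueError("traces must be (n_trials, n_channels, n_samples)")
        if self.control_traces.shape[1:] != self.test_traces.shape[1:]:
            raise ValueError("control and test snippets must share shape")


@dataclass
class CollisionResult:
    window_ms: tuple[float, float] | None
    cutoff: float | None
    p_control: float
    p_test: float
    chi2_p: float
    latency_ms: float
    jitter_ms: float
    passed: bool
    exact_test_used: bool = False
    underpowered: bool = False
    failure_reason: str | None = None


@dataclass
class DirectTagResult:
    latency_ms: float
    jitter_ms: float
    waveform_r: float
    pathway: str
    passed: bool


class NoCandidateResponse(RuntimeError):
    """No dissociation between averaged control and test traces."""


def find_response_window(
    avg_control,
    avg_test,
    fs: float,
    stim_sample: int,
    n_sigma: float = 5.0,
    min_width_ms: float = 0.2,
    max_latency_ms: float = MAX_ANTIDROMIC_LATENCY_MS,
) -> tuple[float, float]:
    """Locate the antidromic response window on averaged single-channel traces.

    Scans the post-stimulus interval (up to ``max_latency_ms``) for
    contiguous runs where |control − test| exceeds ``n_sigma`` times the
    pre-stimulus SD of the difference for at least ``min_width_ms``; the
    widest such run is returned as (start, end) in ms post-stimulus.
    Sub-threshold gaps shorter than ``min_width_ms`` are bridged first, so
    a biphasic spike whose difference dips through zero between trough and
    rebound is treated as one response, not two.
    """
    c = np.asarray(avg_control, dtype=float)
    t = np.asarray(avg_test, dtype=float)
    if c.shape != t.shape:
        raise ValueError("averaged traces must share length")
    diff = np.abs(c - t)
    if stim_sample < 2:
        raise ValueError("need pre-stimulus samples to estimate noise")
    # Robust (MAD-based) noise scale: the pre-stimulus difference contains
    # the trigger spike of test trials, which must not inflate the bound.
    pre = diff[:stim_sample]
    noise_sd = 1.4826 * np.median(np.abs(pre - np.median(pre)))
    if noise_sd == 0.0:
        noise_sd = max(pre.std(ddof=0), 1e-12)
    limit = min(c.size, stim_sample + int(round(max_latency_ms * fs / 1000.0)))
    above = diff[stim_sample:limit] > n_sigma * noise_sd
    min_run = max(int(round(min_width_ms * fs / 1000.0)), 1)
    # Close brief dips (shorter than the minimum response width).
    idx = np.flatnonzero(above)
    if idx.size:
        gaps = np.flatnonzero(np.diff(idx) > 1)
        for g in gaps:
            lo, hi = idx[g], idx[g + 1]
            if hi - lo - 1 < min_run:
                above[lo : hi + 1] = True
    best = None
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j < above.size and above[j]:
                j += 1
            if j - i >= min_run and (best is None or (j - i) > (best[1] - best[0])):
                best = (i, j)
            i = j
        else:
            i += 1
    if best is None:
        raise NoCandidateResponse("no candidate antidromic response")
    return (best[0] * 1000.0 / fs, best[1] * 1000.0 / fs)


def roc_spike_cutoff(minima_control, minima_noise) -> tuple[float, dict]:
    """Spike-detection threshold from an ROC over in-window minima.

    A trial contains a spike when its in-window minimum lies *below* the
    threshold. Candidate thresholds are the midpoints of consecutive pooled
    sorted values; the one maximizing Youden's J (sensitivity +
    specificity − 1) is returned, the median candidate on ties. Identical
    distributions yield the pooled median, flagged degenerate.
    """
    spikes = np.asarray(minima_control, dtype=float)
    noise = np.asarray(minima_noise, dtype=float)
    if spikes.size == 0 or noise.size == 0:
        raise ValueError("both amplitude lists must be non-empty")
    pooled = np.sort(np.concatenate([spikes, noise]))
    uniq = np.unique(pooled)
    if uniq.size < 2:
        return float(np.median(pooled)), {"degenerate": True, "J": 0.0}
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    js = np.array(
        [np.mean(spikes < thr) + np.mean(noise >= thr) - 1.0 for thr in candidates]
    )
    jmax = js.max()
    if jmax <= 0.0:
        return float(np.median(pooled)), {"degenerate": True, "J": float(jmax)}
    best = np.flatnonzero(np.isclose(js, jmax))
    thr = float(candidates[best[best.size // 2]])
    return thr, {"degenerate": False, "J": float(jmax)}


def _quartiles(values) -> tuple[float, float, float]:
    q1, q2, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return float(q1), float(q2), float(q3)


def _best_channel(ensemble: StimTrialEnsemble, fs: float) -> int:
    """Channel with the largest post-stimulus control/test dissociation."""
    avg_c = ensemble.control_traces.mean(axis=0)
    avg_t = ensemble.test_traces.mean(axis=0)
    s = ensemble.stim_sample
    limit = min(avg_c.shape[1], s + int(round(MAX_ANTIDROMIC_LATENCY_MS * fs / 1000.0)))
    score = np.abs(avg_c[:, s:limit] - avg_t[:, s:limit]).max(axis=1)
    return int(np.argmax(score))


def collision_test(
    ensemble: StimTrialEnsemble,
    n_sigma: float = 5.0,
    alpha: float = 0.05,
    min_trials: int = 10,
) -> CollisionResult:
    """Full antidromic collision test on a stimulus-trial ensemble.

    Window finding and ROC thresholding run on the channel with the largest
    control/test dissociation; spike/no-spike counts feed a 2×2 chi-square
    (Fisher's exact test, flagged, when an expected cell count is below 5).
    A window-finding failure is returned as a non-identification, not
    raised.
    """
    n_ctrl = ensemble.control_traces.shape[0]
    n_test = ensemble.test_traces.shape[0]
    underpowered = n_ctrl < min_trials or n_test < min_trials
    fs = ensemble.fs
    ch = _best_channel(ensemble, fs)
    avg_c = ensemble.control_traces[:, ch, :].mean(axis=0)
    avg_t = ensemble.test_traces[:, ch, :].mean(axis=0)
    try:
        win = find_response_window(avg_c, avg_t, fs, ensemble.stim_sample, n_sigma=n_sigma)
    except NoCandidateResponse as e:
        return CollisionResult(
            window_ms=None, cutoff=None, p_control=np.nan, p_test=np.nan,
            chi2_p=np.nan, latency_ms=np.nan, jitter_ms=np.nan, passed=False,
            underpowered=underpowered, failure_reason=str(e),
        )
    s = ensemble.stim_sample
    lo = s + int(round(win[0] * fs / 1000.0))
    hi = s + int(round(win[1] * fs / 1000.0))
    width = hi - lo
    ctrl_min = ensemble.control_traces[:, ch, lo:hi].min(axis=1)
    test_min = ensemble.test_traces[:, ch, lo:hi].min(axis=1)
    # Negative class: pre-stimulus segments of the same width from all trials.
    pre = np.concatenate(
        [ensemble.control_traces[:, ch, :s], ensemble.test_traces[:, ch, :s]], axis=0
    )
    n_seg = s // width
    if n_seg == 0:
        noise_min = pre.min(axis=1)
    else:
        segs = pre[:, s - n_seg * width : s].reshape(pre.shape[0], n_seg, width)
        noise_min = segs.min(axis=2).ravel()
    cutoff, _roc = roc_spike_cutoff(ctrl_min, noise_min)
    ctrl_spike = ctrl_min < cutoff
    test_spike = test_min < cutoff
    p_control = float(ctrl_spike.mean())
    p_test = float(test_spike.mean())
    table = np.array(
        [
            [ctrl_spike.sum(), n_ctrl - ctrl_spike.sum()],
            [test_spike.sum(), n_test - test_spike.sum()],
        ]
    )
    exact = False
    expected = stats.contingency.expected_freq(table) if table.sum() else None
    if expected is not None and (expected < 5).any():
        _, chi2_p = stats.fisher_exact(table)
        exact = True
    else:
        chi2, chi2_p, _, _ = stats.chi2_contingency(table, correction=False)
    # Latency/jitter from in-window most-negative-point times of control spikes.
    if ctrl_spike.any():
        peak_idx = ensemble.control_traces[ctrl_spike, ch, lo:hi].argmin(axis=1)
        peak_ms = (lo + peak_idx - s) * 1000.0 / fs
        q1, q2, q3 = _quartiles(peak_ms)
        latency, jitter = q2, q3 - q1
    else:
        latency, jitter = np.nan, np.nan
    passed = (
        not underpowered
        and p_control > 0.5
        and p_test < p_control / 2.0
        and chi2_p < alpha
        and latency < MAX_ANTIDROMIC_LATENCY_MS
        and jitter < MAX_ANTIDROMIC_JITTER_MS
    )
    return CollisionResult(
        window_ms=win,
        cutoff=cutoff,
        p_control=p_control,
        p_test=p_test,
        chi2_p=float(chi2_p),
        latency_ms=float(latency),
        jitter_ms=float(jitter),
        passed=bool(passed),
        exact_test_used=exact,
        underpowered=underpowered,
    )


def direct_tag(
    light_waveform: np.ndarray,
    light_peak_times_ms,
    spont_waveform: np.ndarray,
    fs: float,
    pathway: str,
) -> DirectTagResult:
    """Direct light-evoked tagging by latency, jitter and waveform similarity.

    ``light_waveform`` and ``spont_waveform`` are mean 4-channel waveforms
    of shape (n_channels, n_samples) sampled identically with the spike
    peak centered; the Pearson correlation is computed over the
    concatenated ±0.125 ms windows around each channel's shared peak.
    """
    lw = np.asarray(light_waveform, dtype=float)
    sw = np.asarray(spont_waveform, dtype=float)
    if lw.ndim != 2 or sw.shape != lw.shape:
        raise ValueError("waveforms must be equal-shape (n_channels, n_samples) arrays")
    if pathway not in DIRECT_LATENCY_LIMIT_MS:
        raise ValueError(f"unknown pathway {pathway!r}")
    half = int(round(WAVEFORM_HALF_WINDOW_MS * fs / 1000.0))
    # Peak defined on the largest-amplitude channel of the spontaneous waveform.
    ch = int(np.argmax(np.abs(sw).max(axis=1)))
    peak = int(np.argmin(sw[ch]))
    lo, hi = peak - half, peak + half + 1
    if lo < 0 or hi > sw.shape[1]:
        raise ValueError("±0.125 ms window around the peak is not available")
    r = float(stats.pearsonr(lw[:, lo:hi].ravel(), sw[:, lo:hi].ravel())[0])
    q1, q2, q3 = _quartiles(np.asarray(list(light_peak_times_ms), dtype=float))
    latency, jitter = q2, q3 - q1
    passed = (
        latency < DIRECT_LATENCY_LIMIT_MS[pathway]
        and jitter < DIRECT_JITTER_LIMIT_MS
        and r > DIRECT_WAVEFORM_R_MIN
    )
    return DirectTagResult(
        latency_ms=latency, jitter_ms=jitter, waveform_r=r, pathway=pathway, passed=bool(passed)
    )


def frequency_following_check(paired_pulse_spikes: np.ndarray) -> bool:
    """Advisory high-frequency-following check.

    ``paired_pulse_spikes`` is a boolean (n_trials, 2) array marking an
    in-window spike after each pulse of a high-frequency pair; the check
    passes when both pulses evoke spikes in more than 50% of trials.
    """
    x = np.asarray(paired_pulse_spikes, dtype=bool)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("expected (n_trials, 2) boolean array")
    return bool(x.all(axis=1).mean() > 0.5)
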