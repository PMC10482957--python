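"""Peri-event firing statistics and reward-rate correlation analyses.

Peri-event time histograms use 20 ms bins smoothed by a 20 ms sliding
window advanced in 10 ms steps. A unit is task-related when trial-by-trial
firing rates in any task window (Go: 0–0.3 s after the Go cue; movement:
0–0.3 s after movement onset; outcome: 0–0.5 s after tone onset) differ
from the baseline (2–3 s before the Go cue) by a Wilcoxon rank-sum test.
Window rates are z-scored against the across-trial baseline mean and SD;
per-unit Pearson correlations between z-scored activity and the trailing
reward rate summarize reward-expectation coupling, with population-level
Wilcoxon signed-rank tests of the r distribution against zero and Fisher
z comparisons (Bonferroni-corrected) between populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

BIN_WIDTH_S = 0.020
SMOOTH_STEP_S = 0.010
BASELINE_WINDOW_S = (-3.0, -2.0)  # relative to Go cue
GO_WINDOW_S = (0.0, 0.3)
MOVEMENT_WINDOW_S = (0.0, 0.3)
OUTCOME_WINDOW_S = (0.0, 0.5)
PREFERENCE_MIN_RELATIVE_DIFF = 0.05


@dataclass
class PETH:
    """Smoothed peri-event time histogram.

    ``rate`` holds firing rates of 20 ms windows evaluated every 10 ms
    (``bin_centers`` are the window centers); ``raw_rate`` holds the
    underlying non-overlapping 20 ms bins, which integrate exactly to the
    per-trial spike count over the span.
    """

    bin_centers: np.ndarray
    rate: np.ndarray
    raw_bin_centers: np.ndarray
    raw_rate: np.ndarray
    n_trials: int
    event: str = ""


def build_peth(
    spikes,
    events,
    span: tuple[float, float],
    bin_width: float = BIN_WIDTH_S,
    step: float = SMOOTH_STEP_S,
    event_name: str = "",
) -> PETH:
    """Trial-averaged firing rate aligned to ``events`` over ``span`` seconds.

    Empty spike trains are allowed and yield an all-zero PETH.
    """
    events = np.asarray(list(events), dtype=float)
    if events.size == 0:
        raise ValueError("events must be non-empty")
    spikes = np.asarray(spikes, dtype=float)
    lo, hi = span
    rel = (spikes[None, :] - events[:, None]).ravel() if spikes.size else np.empty(0)
    rel = rel[(rel >= lo) & (rel < hi)]
    n_trials = events.size
    # Raw non-overlapping bins.
    n_raw = int(round((hi - lo) / bin_width))
    raw_edges = lo + np.arange(n_raw + 1) * bin_width
    raw_counts, _ = np.histogram(rel, bins=raw_edges)
    raw_rate = raw_counts / (n_trials * bin_width)
    raw_centers = (raw_edges[:-1] + raw_edges[1:]) / 2.0
    # Smoothed: 20 ms windows advanced every 10 ms.
    starts = lo + np.arange(int(round((hi - lo - bin_width) / step)) + 1) * step
    sm_rate = np.array(
        [np.count_nonzero((rel >= s) & (rel < s + bin_width)) for s in starts]
    ) / (n_trials * bin_width)
    sm_centers = starts + bin_width / 2.0
    return PETH(
        bin_centers=sm_centers,
        rate=sm_rate,
        raw_bin_centers=raw_centers,
        raw_rate=raw_rate,
        n_trials=n_trials,
        event=event_name,
    )


def window_rates(spikes, events, window: tuple[float, float]) -> np.ndarray:
    """Per-trial firing rate (raw count / width) in ``window`` around each event."""
    spikes = np.asarray(spikes, dtype=float)
    events = np.asarray(list(events), dtype=float)
    lo, hi = window
    width = hi - lo
    counts = np.array(
        [np.count_nonzero((spikes >= ev + lo) & (spikes < ev + hi)) for ev in events]
    )
    return counts / width


@dataclass
class WindowStats:
    """Trial-by-trial window rates and baseline-referenced z-values for one unit."""

    baseline: np.ndarray
    go: np.ndarray
    movement: np.ndarray
    outcome: np.ndarray
    z_go: np.ndarray | None = None
    z_movement: np.ndarray | None = None
    z_outcome: np.ndarray | None = None
    baseline_sd_zero: bool = False

    def __post_init__(self) -> None:
        mu = self.baseline.mean()
        sd = self.baseline.std(ddof=0)
        if sd == 0:
            self.baseline_sd_zero = True
            return
        self.z_go = (self.go - mu) / sd
        self.z_movement = (self.movement - mu) / sd
        self.z_outcome = (self.outcome - mu) / sd


def compute_window_stats(spikes, session) -> WindowStats:
    """Window rates for one unit over a session's Go/movement/outcome events."""
    df = session.to_frame() if hasattr(session, "to_frame") else session
    go = df["go_time"].to_numpy(dtype=float)
    mv = df["movement_onset_time"].to_numpy(dtype=float)
    tone = df["outcome_tone_time"].to_numpy(dtype=float)
    return WindowStats(
        baseline=window_rates(spikes, go, BASELINE_WINDOW_S),
        go=window_rates(spikes, go, GO_WINDOW_S),
        movement=window_rates(spikes, mv, MOVEMENT_WINDOW_S),
        outcome=window_rates(spikes, tone, OUTCOME_WINDOW_S),
    )


def task_related_test(stats_: WindowStats, alpha: float = 0.05) -> dict:
    """Wilcoxon rank-sum of each task window's trial rates vs baseline rates.

    Returns per-window p-values and significance flags plus an overall
    ``task_related`` flag (any window significant). Fewer than two trials in
    any sample makes the unit untestable.
    """
    windows = {"go": stats_.go, "movement": stats_.movement, "outcome": stats_.outcome}
    if stats_.baseline.size < 2 or any(w.size < 2 for w in windows.values()):
        return {"testable": False, "task_related": False, "p": {}, "significant": {}}
    p = {}
    sig = {}
    for name, w in windows.items():
        p[name] = float(stats.ranksums(w, stats_.baseline).pvalue)
        sig[name] = p[name] < alpha
    return {"testable": True, "task_related": any(sig.values()), "p": p, "significant": sig}


def action_preference(push_movement_rates, pull_movement_rates) -> str:
    """Preferred action by the ≥5% movement-window rate-difference rule."""
    push = np.asarray(push_movement_rates, dtype=float)
    pull = np.asarray(pull_movement_rates, dtype=float)
    if push.size < 1 or pull.size < 1:
        raise ValueError("both conditions need at least one trial")
    m_push, m_pull = push.mean(), pull.mean()
    top = max(m_push, m_pull)
    if top == 0.0:
        return "none"
    if abs(m_push - m_pull) / top < PREFERENCE_MIN_RELATIVE_DIFF:
        return "none"
    return "push" if m_push > m_pull else "pull"


@dataclass
class CorrelationResult:
    r: float
    p: float
    n_trials: int
    condition: str = ""
    window: str = ""
    defined: bool = True


def reward_rate_correlation(
    z_values, reward_rates, condition_mask=None, condition: str = "", window: str = ""
) -> CorrelationResult:
    """Pearson correlation of per-trial z-scored activity with the reward rate.

    Trials with undefined (NaN) reward rate are excluded; an optional
    boolean mask restricts to one outcome condition. Zero variance in
    either variable yields an undefined (excluded) result.
    """
    z = np.asarray(z_values, dtype=float)
    rr = np.asarray(reward_rates, dtype=float)
    if z.shape != rr.shape:
        raise ValueError("z_values and reward_rates must align")
    keep = np.isfinite(rr) & np.isfinite(z)
    if condition_mask is not None:
        keep &= np.asarray(condition_mask, dtype=bool)
    z, rr = z[keep], rr[keep]
    n = z.size
    if n < 4:
        raise ValueError("need at least 4 trials with defined reward rate")
    if np.var(z) == 0.0 or np.var(rr) == 0.0:
        return CorrelationResult(
            r=np.nan, p=np.nan, n_trials=n, condition=condition, window=window, defined=False
        )
    r, p = stats.pearsonr(z, rr)
    return CorrelationResult(
        r=float(r), p=float(p), n_trials=n, condition=condition, window=window
    )


def population_r_test(r_values) -> float:
    """One-sample Wilcoxon signed-rank test of a population's r values against 0.

    A population of identical nonzero r values is degenerate for rank
    methods (all ranks tie) but still carries consistent sign information;
    it is flagged with a warning and tested with the exact distribution.
    """
    r = np.asarray([v for v in r_values if np.isfinite(v)], dtype=float)
    if r.size < 5:
        raise ValueError("need at least 5 finite r values")
    if np.all(r == 0.0):
        raise ValueError("degenerate: all r values are exactly 0")
    if np.all(r == r[0]):
        warnings.warn("all r values identical; signed-rank test degenerate to a sign test")
        return float(stats.wilcoxon(r, mode="exact").pvalue)
    return float(stats.wilcoxon(r).pvalue)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int, m_comparisons: int = 1):
    """Fisher z comparison of two Pearson correlations with Bonferroni correction.

    z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3)); the two-sided
    normal p is multiplied by ``m_comparisons`` and capped at 1.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("sample sizes must exceed 3")
    if abs(r1) >= 1.0 or abs(r2) >= 1.0:
        raise ValueError("|r| must be < 1 (atanh diverges)")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(1.0, m_comparisons * p))


def outcome_contrast(
    rates_rewarded: np.ndarray, rates_nonrewarded: np.ndarray, alpha: float = 0.01
) -> np.ndarray:
    """Per-bin two-sample t-test mask of rewarded vs non-rewarded trial rates.

    Inputs are (n_trials, n_bins) matrices of per-trial bin rates; returns
    a boolean mask of bins significant at ``alpha``.
    """
    a = np.asarray(rates_rewarded, dtype=float)
    b = np.asarray(rates_nonrewarded, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("inputs must be (n_trials, n_bins) with matching bins")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 trials per condition")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.ttest_ind(a, b, axis=0).pvalue
    mask = np.asarray(p) < alpha
    mask[~np.isfinite(np.asarray(p))] = False
    return mask


def per_trial_bin_rates(spikes, events, span, bin_width: float = BIN_WIDTH_S) -> np.ndarray:
    """(n_trials, n_bins) matrix of per-trial firing rates in raw PETH bins."""
    spikes = np.asarray(spikes, dtype=float)
    events = np.asarray(list(events), dtype=float)
    lo, hi = span
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + np.arange(n_bins + 1) * bin_width
    out = np.empty((events.size, n_bins))
    for i, ev in enumerate(events):
        rel = spikes[(spikes >= ev + lo) & (spikes < ev + hi)] - ev
        out[i], _ = np.histogram(rel, bins=edges)
    return out / bin_width
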