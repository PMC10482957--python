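"""Fiber-photometry (dLight) signal chain.

Raw two-channel fluorescence — a dopamine-sensitive 470 nm channel and a
motion/bleach control 405 nm (isosbestic) channel sampled at 1 kHz — is
processed to a normalized ΔF/F series:

1. per-channel detrending by a least-squares exponential + linear fit
   (photobleaching model ``a·exp(-t/τ) + b·t + c``);
2. an ordinary-least-squares mapping of the 405 channel onto the 470
   channel; ΔF/F = (470 − fit(405)) / fit(405);
3. block-mean downsampling to the analysis rate (40 Hz);
4. whole-session z-scoring.

Event alignment and window statistics operate on the analysis-rate series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

GO_WINDOW_S = (0.0, 0.3)
MOVEMENT_WINDOW_S = (0.0, 0.3)
OUTCOME_WINDOW_S = (0.0, 0.5)

#: Floor on the fitted isosbestic denominator, as a fraction of its RMS.
DENOMINATOR_FLOOR_FRACTION = 0.01


@dataclass
class PhotometryTrace:
    """Paired 470/405 fluorescence channels with sampling metadata."""

    signal_470: np.ndarray
    isosbestic_405: np.ndarray
    fs_acquired: float = 1000.0
    fs_analysis: float = 40.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.signal_470 = np.asarray(self.signal_470, dtype=float)
        self.isosbestic_405 = np.asarray(self.isosbestic_405, dtype=float)
        if self.signal_470.shape != self.isosbestic_405.shape:
            raise ValueError("channels must share length")
        ratio = self.fs_acquired / self.fs_analysis
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("fs_acquired must be divisible by fs_analysis")


@dataclass
class NormalizedSignal:
    """ΔF/F and z-scored series on the analysis clock."""

    dff: np.ndarray
    z: np.ndarray
    fs: float
    t0: float = 0.0


@dataclass
class DetrendResult:
    residual: np.ndarray
    fitted: np.ndarray
    params: dict
    linear_fallback: bool = False


def _decay_model(t, a, tau, b, c):
    return a * np.exp(-t / tau) + b * t + c


def remove_decay(channel, fs: float = 1000.0, robust_iters: int = 2) -> DetrendResult:
    """Fit and subtract exponential + linear signal decay.

    Fits ``a·exp(-t/τ) + b·t + c`` by nonlinear least squares and returns
    the residual together with the fitted curve and parameters. Positive
    outliers (release transients riding on the bleaching baseline) are
    iteratively masked out of the fit so their amplitude is not absorbed
    into the trend. A non-convergent fit falls back to a linear-only fit,
    flagged via ``linear_fallback``.
    """
    x = np.asarray(channel, dtype=float)
    if x.size < 4:
        raise ValueError("series shorter than the number of fit parameters")
    t = np.arange(x.size) / fs
    span = t[-1] if t[-1] > 0 else 1.0
    # Decimate for the fit itself (the trend is slow); evaluate on the full grid.
    stride = max(x.size // 100_000, 1)
    amp0 = max(x[: max(x.size // 20, 1)].mean() - x[-max(x.size // 20, 1):].mean(), 1e-6)
    p0 = (amp0, span / 3.0, 0.0, float(x[-max(x.size // 20, 1):].mean()))
    keep = np.ones(t[::stride].size, dtype=bool)
    tf, xf = t[::stride], x[::stride]
    try:
        popt = p0
        for _ in range(max(robust_iters, 0) + 1):
            popt, _ = curve_fit(
                _decay_model,
                tf[keep],
                xf[keep],
                p0=popt,
                bounds=(
                    [-np.inf, span * 1e-4, -np.inf, -np.inf],
                    [np.inf, span * 1e3, np.inf, np.inf],
                ),
                maxfev=20000,
            )
            res = xf - _decay_model(tf, *popt)
            mad = 1.4826 * np.median(np.abs(res - np.median(res)))
            if mad == 0.0:
                break
            keep = res < 2.0 * mad  # one-sided: transients are positive
        fitted = _decay_model(t, *popt)
        # Recentre on the baseline: transient tails below the mask threshold
        # bias the trend upward; the residual median is robust to them.
        offset = float(np.median(x - fitted))
        fitted = fitted + offset
        return DetrendResult(
            residual=x - fitted,
            fitted=fitted,
            params={"a": popt[0], "tau": popt[1], "b": popt[2], "c": popt[3] + offset},
        )
    except (RuntimeError, ValueError):
        coef = np.polyfit(t, x, 1)
        fitted = np.polyval(coef, t)
        return DetrendResult(
            residual=x - fitted,
            fitted=fitted,
            params={"a": 0.0, "tau": np.nan, "b": coef[0], "c": coef[1]},
            linear_fallback=True,
        )


class DenominatorInstability(RuntimeError):
    """Fitted isosbestic series too close to zero for a stable ΔF/F division."""


def isosbestic_dff(sig, iso) -> np.ndarray:
    """Isosbestic-corrected ΔF/F.

    An OLS line maps the 405 channel onto the 470 channel over the whole
    session; ΔF/F = (470 − fit(405)) / fit(405). A near-constant isosbestic
    channel degenerates the regression to the 470 mean, which is the
    correct limit (no shared artifact to remove).
    """
    sig = np.asarray(sig, dtype=float)
    iso = np.asarray(iso, dtype=float)
    if sig.shape != iso.shape:
        raise ValueError("channels must share length")
    if np.var(iso) < 1e-12 * max(np.var(sig), 1.0) + 1e-300:
        fitted = np.full_like(sig, sig.mean())
    else:
        slope, intercept = np.polyfit(iso, sig, 1)
        fitted = slope * iso + intercept
    floor = DENOMINATOR_FLOOR_FRACTION * max(float(np.sqrt(np.mean(fitted**2))), 1e-12)
    if np.any(np.abs(fitted) < floor):
        raise DenominatorInstability(
            "fitted 405 series approaches zero; ΔF/F division is unstable"
        )
    return (sig - fitted) / fitted


def downsample(series, fs_in: float, fs_out: float) -> np.ndarray:
    """Block-mean downsampling; ``fs_in`` must be an integer multiple of ``fs_out``."""
    ratio = fs_in / fs_out
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("fs_in must be divisible by fs_out")
    k = int(round(ratio))
    x = np.asarray(series, dtype=float)
    n = (x.size // k) * k
    return x[:n].reshape(-1, k).mean(axis=1)


def process_trace(trace: PhotometryTrace) -> NormalizedSignal:
    """Full chain: detrend both channels, isosbestic ΔF/F, downsample, z-score.

    Each channel's mean fitted baseline level is added back after
    detrending so the isosbestic regression and the ΔF/F denominator
    operate at the channel's baseline fluorescence (the session mean of
    the fitted trend is identifiable even when the individual decay
    parameters trade off on short recordings).
    """
    det_sig = remove_decay(trace.signal_470, fs=trace.fs_acquired)
    det_iso = remove_decay(trace.isosbestic_405, fs=trace.fs_acquired)
    sig = det_sig.residual + float(det_sig.fitted.mean())
    iso = det_iso.residual + float(det_iso.fitted.mean())
    dff = isosbestic_dff(sig, iso)
    dff_ds = downsample(dff, trace.fs_acquired, trace.fs_analysis)
    sd = dff_ds.std(ddof=0)
    z = (dff_ds - dff_ds.mean()) / sd if sd > 0 else np.zeros_like(dff_ds)
    return NormalizedSignal(dff=dff_ds, z=z, fs=trace.fs_analysis, t0=trace.t0)


def align_to_events(
    signal: NormalizedSignal,
    events,
    window: tuple[float, float],
    use: str = "z",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract per-event snippets of the analysis-rate series.

    Returns ``(matrix, time_axis, kept_events)``; rows are trials, the
    column at relative time 0 is the event sample. Events whose window
    falls outside the recording are dropped.
    """
    events = np.asarray(list(events), dtype=float)
    if events.size == 0:
        raise ValueError("empty event list")
    x = signal.z if use == "z" else signal.dff
    pre, post = window
    n_pre = int(round(pre * signal.fs))
    n_post = int(round(post * signal.fs))
    rows = []
    kept = []
    for ev in events:
        idx = int(round((ev - signal.t0) * signal.fs))
        lo, hi = idx - n_pre, idx + n_post + 1
        if lo < 0 or hi > x.size:
            continue
        rows.append(x[lo:hi])
        kept.append(ev)
    if not rows:
        raise ValueError("no events fall inside the recorded span")
    taxis = (np.arange(-n_pre, n_post + 1)) / signal.fs
    return np.vstack(rows), taxis, np.asarray(kept)


def window_values(aligned: np.ndarray, taxis: np.ndarray, interval: tuple[float, float]) -> np.ndarray:
    """Per-trial mean of the aligned matrix over ``interval`` (half-open [start, end))."""
    lo, hi = interval
    mask = (taxis >= lo) & (taxis < hi)
    if not mask.any():
        raise ValueError("window lies outside the snippet span")
    return aligned[:, mask].mean(axis=1)
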