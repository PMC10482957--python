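# Methods

This note documents the models, parameters, numerical choices and known
limitations of the `nsr` toolkit. It describes what the code computes and
why each open design point was resolved the way it was; every empirical
figure quoted here is produced by the package's own tests or the
acceptance script.

## Task simulator (`nsr.task_sim`)

A session is simulated trial by trial. Each trial draws a center-hold
duration (0.4 ± 0.1 s uniform), a reaction time and a movement time
(log-normal; medians 0.30 s and 0.25 s, shape parameters 0.25 and 0.20),
giving ordered Go / movement-onset / outcome-tone timestamps; rewarded
trials deliver reward 0.3 s after tone onset. The reaction/movement
distributions are placeholders with realistic magnitudes — the simulator
makes no claims about empirical reaction-time distributions, only about
event ordering and task contingencies.

Outcomes are Bernoulli: 0.70 for the block-congruent action, 0.10
otherwise. The block reverses when the completed block holds ≥ 30 correct
choices *and* the correct rate over the last 10 trials strictly exceeds
0.79. The strict comparison follows the "more than 79%" phrasing of the
task rules; the alternative "≥ 79%" reading changes nothing for 10-trial
windows except at exactly 7.9/10, which cannot occur.

Choice policies are logistic over signed past-outcome regressors. The
coding (+1 rewarded push, −1 rewarded pull, 0 otherwise; analogous for
unrewarded trials) makes a positive reward weight mean "stay after
reward" and a negative no-reward weight mean "switch after no reward".
Histories shorter than the model order pad regressors with zeros — there
are no pre-session pseudo-trials. The stock `stay_biased_params()` agent
uses geometrically decaying reward weights (3.0 × 0.5^j) and a single
lose-switch weight (−0.8 at lag 1); it completes a block in roughly 35–50
trials, comparable to a trained subject.

## Behavioral statistics (`nsr.behavior`)

**Reward rate.** Mean of the five previous outcomes, excluding the
current trial; trials 0–4 are flagged undefined and excluded from every
downstream analysis rather than imputed. Values live on the exact grid
{0, 0.2, 0.4, 0.6, 0.8, 1.0}; switch-probability tables bin by these
grid values, not ranges.

**Choice regression.** Maximum-likelihood logistic fit (statsmodels) of
the push indicator on the signed regressors, per session. Wald standard
errors and p-values are reported; quasi-separation (non-finite standard
errors or |β| > 20) sets a `separation_flag` instead of silently
returning a diverged fit. Multi-session summaries report mean ± SD of
coefficients across sessions. Exchanging the push/pull labels leaves all
β^R, β^N invariant and flips the sign of the intercept (a property test
enforces this).

**Movement-onset detection.** The hold-period baseline gives μ and σ.
Two one-sided CUSUM statistics on signed deviations,
`S±_t = max(0, S±_{t−1} ± (x_t − μ) − k)` with reference value `k = 2σ`,
are compared against the 3σ bound; onset is the first post-Go crossing of
either. The reference value was chosen so that the statistic is strongly
mean-reverting under hold noise: measured false-alarm rates on pure
Gaussian noise are 0.1% over 300 post-Go samples and 0.6% over 1000,
while a 10σ step is still detected at its first sample and a 5σ-per-
sample ramp within two samples (genuine lever excursions are tens of
baseline SDs). An absolute-deviation accumulator at the same 3σ bound was
rejected because its noise-driven walk has only −0.2σ drift per step and
false-alarms on half of all pure-noise trials. A zero-variance baseline
falls back to exact-departure detection.

## Photometry chain (`nsr.photometry`)

Processing order: per-channel detrend → isosbestic regression → ΔF/F →
block-mean downsample (1 kHz → 40 Hz) → whole-session z-score.

**Detrend.** Nonlinear least squares of `a·exp(−t/τ) + b·t + c` per
channel. Release transients ride positively on the baseline, so the fit
iteratively masks samples more than 2 MAD above the running fit (two
refits) and finally re-centres the trend on the residual median;
otherwise the trend absorbs 10–16% of transient amplitude at realistic
transient duty cycles. On a noiseless synthetic decay (a = 100,
τ = 300 s, b = −0.01) parameters are recovered to well under 1%. A
non-convergent fit falls back to linear-only, flagged. For the fit the
series is internally decimated to ≤ 100k points (the trend is slow);
residuals are evaluated at full rate.

**Isosbestic correction.** Ordinary least squares maps the detrended 405
channel onto the detrended 470 channel over the whole session (robust
regression is deliberately not the default — the simplest reading of a
"linear fit"); ΔF/F = (470 − fit(405)) / fit(405). Because the asymptote
`c` is unidentifiable when the session is shorter than the bleach time
constant, the composed chain adds back the *mean of the fitted trend*
(identifiable in-sample) rather than `c` before the regression. A fitted
denominator within 1% of zero (relative to its RMS) aborts with a
diagnostic. A near-constant isosbestic channel degenerates the regression
to the 470 mean, which is the correct limit.

**Downsampling** is a block mean over 25 consecutive samples. At these
bandwidths (sub-second transients sampled at 1 kHz, analyzed at 40 Hz)
anti-alias filtering changes nothing measurable and is omitted.

**Normalization.** z-scores use the whole-session ΔF/F mean and SD. A
pre-event-baseline z-score was considered and rejected for the session
statistic because the reward-rate analyses operate on per-trial window
values, which are themselves baseline-referenced at the aligned-average
stage.

Amplitude bookkeeping: the chain measures ΔF/F relative to the session
baseline, so constant offsets from overlapping transient tails subtract
out only when window values are referenced to a local pre-event baseline.
The closure test therefore measures recovered amplitude as
(aligned-average peak) − (mean over −0.5…−0.2 s pre-event); with the
generator's defaults the recovered amplitude is within ~3% of the
injected value (criterion: 10%).

## Optogenetic identification (`nsr.optotag`)

**Collision test.** The response window is the widest contiguous
post-stimulus run (≤ 25 ms) where |avg control − avg test| exceeds 5× the
robust (MAD-based) pre-stimulus noise SD for ≥ 0.2 ms; sub-threshold dips
shorter than 0.2 ms are bridged so a biphasic spike is one response. The
multiplier is deliberately high: a genuine antidromic spike exceeds the
averaged-noise floor by one to two orders of magnitude, while at 3σ the
window-finder locks onto noise ripples and the subsequent ROC capitalizes
on the selected window — a circularity that produced spurious
identifications of non-projecting units in simulation. The MAD noise
scale ignores the trigger spike present in test-trace averages.

The spike/no-spike threshold maximizes Youden's J over midpoints of the
pooled sorted in-window minima (spike class: control trials; noise class:
pre-stimulus segments of the same width from all trials). Ties take the
median maximizing candidate; identical distributions return the pooled
median, flagged degenerate. The 2×2 chi-square is computed without
continuity correction; an expected cell below 5 switches to Fisher's
exact test, flagged. Latency is the median and jitter the Q3 − Q1 of
in-window minimum times (linear-interpolation quartiles). Identification
requires control spike probability > 0.5, test probability < half of
control, chi-square p < 0.05, latency < 25 ms, jitter < 0.5 ms, and at
least 10 trials per condition. Channel choice: the channel with the
largest post-stimulus control/test dissociation. The result is invariant
to channel permutation and uniform amplitude scaling (tested).

**Direct tagging** correlates the concatenated 4-channel waveforms over
±0.125 ms around the spontaneous waveform's peak (peak defined on the
largest-amplitude channel), with pathway-specific latency limits (8 ms
striatonigral, 10 ms striatopallidal), jitter < 1 ms, r > 0.9. The
paired-pulse frequency-following check is advisory: both pulses must
evoke in-window spikes in > 50% of trials.

## Cell-type classification (`nsr.classify`)

SNc units: spike duration < 800 µs ⇒ putative GABAergic, else putative
dopaminergic (the boundary value 800 µs goes to the dopaminergic side —
the rule is "narrow < 800"). Mediolateral split at 1.8 mm (boundary to
lateral); positions outside 0.8–2.4 mm are errors.

Striatal units: k-means (k = 3, 50 restarts, deterministic seed, best
inertia) on z-scored (ongoing rate, peak-to-valley width, CV of ISI) —
standardization is required because Hz, µs and a dimensionless CV share
no scale. Clusters are named by centroid width ordering (FSI narrowest,
SPN widest, TAN between), which matches the known physiology and is
stable on separable data; mean silhouette is reported alongside. On the
default synthetic population the recovered labels match ground truth
> 95% with silhouette ≈ 0.6–0.75.

## Peri-event statistics (`nsr.peth`)

PETHs count spikes in 20 ms windows evaluated on a 10 ms step grid (the
literal reading of "20 ms bins smoothed by a 20 ms sliding window with a
10 ms step"); the raw non-overlapping 20 ms bins are also exposed and
integrate exactly to (in-span spikes)/(trials). Task windows: baseline
2–3 s before Go, 0.3 s after Go, 0.3 s after movement onset, 0.5 s after
tone onset; per-trial rates are raw counts/width, not smoothed values.
Task-relatedness is a Wilcoxon rank-sum of each window's per-trial rates
against baseline at α = 0.05 two-sided (conventional default; exposed as
a parameter), any significant window qualifying the unit. Units with zero
baseline SD are excluded from z-based analyses with a logged reason.
Action preference requires a ≥ 5% relative difference of mean
movement-window rates; only preferred-action trials feed the reward-rate
correlations. Pearson p-values are two-sided with no per-unit multiple-
testing correction (population-level inference uses the r distribution);
the count of significant units is reported with the α used.

The population test of r values against zero is implemented as a
one-sample Wilcoxon signed-rank (a literal two-sample rank-sum against
the constant 0 is not defined); an all-identical nonzero r population is
degenerate for rank methods and is flagged with a warning while still
returning the exact (sign-test) p. Fisher z comparisons use the closed
form with Bonferroni multiplication capped at 1. In simulation the
Fisher p agrees with a 10,000-shuffle permutation comparison to within
0.02 at n = 250 pairs per group; the permutation null is systematically
slightly wider at finite n, so exact agreement is not expected.

## Synthetic generators (`nsr.synth`)

All generators are deterministic functions of (spec, seed).

**Spike trains** are inhomogeneous Poisson on a 1 ms grid: baseline plus
per-event double-exponential kernels (default rise 20 ms, decay 150 ms)
whose gain scales as 1 + coupling × reward rate of the trial, rectified
at zero. An optional absolute dead time produces the sub-Poisson ISI
regularity needed for TAN-like units. No refractoriness is modeled by
default.

**Photometry** combines f0 = 100 a.u., bleach 30·exp(−t/600 s) − 0.002·t,
event transients (rise 50 ms, decay 400 ms) specified in peak-ΔF/F units
over the local baseline, optional slow shared motion artifact, and white
channel noise (SD 0.3 a.u.). The isosbestic channel is the scaled
baseline (gain 0.8) plus a configurable artifact fraction and independent
noise, with no transients. Transients are injected multiplicatively
(fractional fluorescence change) because that is the physical quantity
ΔF/F estimates; an additive-constant injection would make the ground
truth depend on where in the bleach curve a trial falls.

**Collision ensembles** place a biphasic extracellular spike template
(~1.2 ms, amplitude 80 vs noise SD 4, channel gains 1.0/0.6/0.35/0.15) at
a 12 ms conduction latency ± 0.1 ms jitter in control trials; test trials
carry the triggering spontaneous spike 3 ms before the pulse and omit the
evoked spike (collision), with a configurable partial-failure
probability. Background spontaneous spikes (5 Hz) avoid a guard zone of
± (latency + 2 ms) around the pulse, mirroring the experimental
definition of control/test trials. Collision physics is idealized — the
evoked spike is deleted deterministically — because the test's power, not
axonal biophysics, is what the analyses need to see.

**Unit populations** draw class-conditional Gaussian features
(SPN 1.8 Hz / 640 µs / CV 1.35; TAN 5.5 Hz / 490 µs / CV 0.65;
FSI 16 Hz / 210 µs / CV 1.0) with a mix of 36% / 61% / 3%, matching the
relative abundances reported for dorsal-striatal recordings.

**What the generators do not emulate:** drift and unit instability,
correlated population noise, spike-sorting contamination, hemodynamic or
wavelength-dependent motion artifacts beyond a shared additive term, and
licking/orofacial confounds. Passing closure tests therefore demonstrates
correctness of the analysis chain under its stated assumptions, not
robustness to every pathology of real recordings.

## Pipeline and reproducibility (`nsr.config`, `nsr.pipeline`, `nsr.cli`)

A single global seed derives per-stage seeds through
`numpy.random.SeedSequence` in a fixed stage order; no stage reads
ambient entropy. The default end-to-end run uses 300 trials and 12
synthetic units with alternating reward-rate coupling signs — large
enough for every stage to operate and small enough to finish in seconds;
the acceptance-scale checks (20,000-trial regressions, 100-unit
identification sweeps, 5,000-unit calibration) live in the test suite and
acceptance script. The manifest records config, per-stage artifact paths
and SHA-256 hashes; identical config + seed reproduces identical hashes
(tested). Times are serialized in seconds at 1 µs precision; sample
indices are 0-based; windows are half-open [start, end).

## Known limitations

- The logistic agent's quasi-separation on short (< a few hundred trial)
  sessions is flagged, not resolved; penalized (Firth) regression would
  be the next step if short empirical sessions were in scope.
- The ΔF/F denominator is a session-level baseline; slow within-session
  sensitivity changes beyond the exponential+linear model bias amplitudes.
- k-means cluster naming assumes the three striatal types are present;
  populations missing a class will still receive three labels.
- The collision test assumes the candidate cluster is well isolated;
  contaminated clusters violate the all-or-none premise and are outside
  the generator's scope.
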