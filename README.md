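# nsr — nigrostriatal reward-expectation analysis toolkit

`nsr` simulates and analyzes a head-fixed probabilistic push/pull choice
task of the kind used to study how recent reward history shapes action
selection in the nigrostriatal system. It is aimed at systems-neuroscience
researchers who want a tested, reproducible desk-scale implementation of
the full analysis chain — behavioral statistics, fiber-photometry (dLight)
ΔF/F processing, optogenetic unit identification, putative cell-type
classification, and peri-event firing statistics — together with
ground-truth synthetic generators for validating every stage.

## The task and the core statistics

On each trial the subject pushes or pulls a lever after a Go cue. The
action matching the current block is rewarded at 70%, the other at 10%;
the contingency reverses once the subject accumulates **≥ 30 correct
choices** in the block and exceeds a **79% correct rate over the last ten
trials**.

Choice strategy is quantified by a logistic regression of the current
choice on signed past-outcome regressors:

```
ln( P_push(i) / (1 − P_push(i)) )
    = Σ_{j=1..n} β_j^R · Reward(i−j)  +  Σ_{j=1..n} β_j^N · NoReward(i−j)  +  β_0
```

where `Reward(i−j)` is +1 / −1 for a rewarded push / pull on trial `i−j`
(0 if unrewarded), `NoReward` is the analogue for unrewarded trials, and
`n = 8` past trials are included. Positive `β^R` expresses win-stay,
negative `β^N` expresses lose-switch.

Reward expectation is proxied by the **reward rate**: the number of
rewards in the five trials preceding the current one, divided by five
(grid 0, 0.2, …, 1.0; undefined for the first five trials). Neural
analyses correlate z-scored peri-event activity with this quantity per
unit (Pearson r), test r distributions against zero (Wilcoxon signed
rank), and compare populations with Fisher's z (Bonferroni-corrected):

```
z = (atanh r₁ − atanh r₂) / sqrt( 1/(n₁−3) + 1/(n₂−3) )
```

The optogenetic module implements the antidromic spike-collision test
(ROC-derived spike threshold, 2×2 chi-square, latency < 25 ms, jitter
< 0.5 ms) and direct light-evoked tagging (latency < 8 ms striatonigral /
< 10 ms striatopallidal, jitter < 1 ms, 4-channel waveform correlation
r > 0.9).

## Worked example

```python
import numpy as np
from nsr import task_sim, behavior

cfg = task_sim.TaskConfig()                  # 70%/10%, ≥30 correct, >79%/10
params = task_sim.stay_biased_params()       # win-stay / mild lose-switch agent
log = task_sim.run_session(cfg, params, 2000, seed=11)
print(len(log.block_boundaries))             # 52 reversals

fit = behavior.fit_choice_regression(log, n_past=8)
print(np.round(fit.beta_reward[:3], 2))      # [3.43 1.39 0.97]  (truth: 3.0 1.5 0.75)
print(round(fit.beta_noreward[0], 2))        # -0.76             (truth: -0.8)

table = behavior.switch_probability_by_reward_rate(log)
```

The recovered weights sit within ~1.5 standard errors of the generating
policy. The switch-probability table shows the signature of reward
expectation: after a non-rewarded trial the probability of switching
falls monotonically with the reward rate (0.70 at rate 0 down to 0.13 at
rate 1.0 in this session), while after a rewarded trial it stays below
0.03 everywhere.

The same session can drive the neural stages end to end:

```bash
nsr run --seed 7 --out myrun     # simulate → synthesize → analyze, with manifest
nsr simulate --n-trials 2000 --seed 11 --out sess
nsr analyze-behavior sess --out beh
```

`nsr run` writes `manifest.json` (inputs, outputs, SHA-256 hashes, seed);
re-running with the same seed reproduces every artifact bit for bit.

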