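# stoptask

Simulation and analysis of the **probabilistic-context stop-signal task
(SST)** — a response-inhibition paradigm in which participants categorize
pictures (neutral vs. poker) under a 1250 ms deadline while the background
color signals the probability that an auditory stop signal will require them
to cancel the response: green 0%, yellow 17%, orange 25%, red 33%.

The package is aimed at researchers who study **proactive** inhibition (the
anticipatory slowing of responses as stop probability rises) and **reactive**
inhibition (outright stopping, summarized by the stop-signal reaction time,
SSRT). It provides:

* **Exact schedule generation** — 350 go and 82 stop trials in blocks of
  9/18/27 same-context trials with no context repetition, balanced picture
  assignment (36 pictures × 12 repetitions), and event timing (750 ms cue,
  1250 ms picture, 2000 ms grey screen at context changes), plus the
  36-trial training run.
* **An independent horse-race simulator** — go finish times are
  ex-Gaussian(μ + gain·p<sub>ctx</sub>, σ, τ); a stop process with latency
  S ~ N(μ<sub>SSRT</sub>, σ<sub>SSRT</sub>) truncated at 0 races it from the
  stop-signal delay (SSD). The subject responds on a stop trial iff
  G < SSD + S (and G is within the deadline). SSD follows the task's
  1-up/1-down staircase (initial 800 ms, ±25 ms, one staircase per stimulus
  type shared across the stop contexts), which drives
  p[respond|signal] → 0.50.
* **The behavioral analysis chain** — per-level IQR outlier rejection
  (1.5×IQR beyond the quartiles), the proactive slope (OLS of context mean
  go RT on stop probability, ms per unit probability), integration-method
  SSRT (the ⌈p·N⌉-th fastest go RT, misses substituted at 1250 ms, minus
  mean SSD), race-model validity checks (p[respond|signal] near 0.50,
  failed-stop RT < go RT), and the >70%-respond exclusion rule.
* **Group inference** — balanced mixed (split-plot) repeated-measures ANOVA
  with partial η², pairwise context comparisons, and Spearman correlations
  with Bonferroni adjustment (exact permutation p for n ≤ 9).

Analysis follows a statsmodels-style model/results pattern:
`MixedAnova(...).fit()` and `StopSignalStudy(trials).fit()` return results
objects with tables and `summary()`.

## Worked example

```python
import stoptask as st

trials, params = st.simulate_cohort(n_per_group=14, seed=1)   # 14 + 14 subjects
res = st.StopSignalStudy(trials, covariates=params).fit()
print(res.summary())
```

```
subjects: 28 (28 retained, 0 excluded)

Validity (retained subjects, stop contexts pooled)
  mean p[respond|signal]: 0.514
  mean failed-stop RT:    914.7 ms
  mean go RT:             961.1 ms
  independence (failed < go) holds for 28/28 subjects
  mean go RT [green ]:   813.7 ms
  ...
  mean go RT [red   ]:   1004.1 ms
  mean proactive slope:   584.0 ms/unit p
  mean SSRT [neutral]:    189.7 ms
  mean SSRT [poker  ]:    188.8 ms

effect                               F          df         p   partial eta^2
group                             1.62     (1, 26)    0.2148           0.059
context                         513.47     (3, 78)    0.0000           0.952
...
context ordering by mean RT: red > orange > yellow > green

Covariate correlations (Spearman, Bonferroni-adjusted)
  proactive_slope  rho(28) = -0.56, p = 0.002, p_adj = 0.006
```

Reading the output: the staircase held stop-trial responding near 0.50 for
every subject; failed-stop responses are faster than go responses (the
race-model independence signature); go RT climbs monotonically from the
green (0%) to the red (33%) context — that slope, ≈584 ms per unit stop
probability here, is the proactive-inhibition measure; SSRT sits near the
generative stop latency of 200 ms; and the simulated neural covariate is
rank-correlated with the proactive slope, as built into the generator.

The same pipeline runs from the shell:

```bash
stoptask simulate --seed 1 --n-per-group 14 --out run/
stoptask analyze --log run/trials.csv --params run/params.csv --out run/out/
stoptask report --summary run/out/summary.csv
```

Real per-trial logs can be analyzed with `stoptask analyze` as long as they
match the trial-log CSV schema written by `simulate` (one row per trial:
subject, group, context, trial kind, stimulus type, SSD, RT, outcome).

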