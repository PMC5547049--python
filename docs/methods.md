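# Methods

## Task model

The schedule builder reproduces a probabilistic-context stop-signal task.
Four screen-color contexts carry nominal stop-signal probabilities 0
(green), 0.17 (yellow), 0.25 (orange) and 0.33 (red). Trials are grouped in
blocks of 9, 18 or 27 same-context trials; consecutive blocks never share a
context. Each trial is a context cue (750 ms) followed by a picture
(1250 ms, which is also the categorization deadline); context changes insert
a 2000 ms grey screen. Stimuli are 18 neutral and 18 poker pictures, each
shown 12 times.

Per-stimulus trial counts are go 54/45/40/36 and stop 0/9/14/18 across
green/yellow/orange/red. The green go count is 54, not the frequently
quoted 64: with 64 the totals are mutually inconsistent (2·(64+45+40+36) =
370 ≠ 350 go trials; 370 + 82 ≠ 36 pictures × 12 repetitions; and a
128-trial green context cannot be partitioned into blocks of 9/18/27),
whereas 54 satisfies all three constraints simultaneously, giving every
context exactly 108 trials. Any other counts can be configured through
`DesignSpec`. Two published proportions are reproduced as counts, not
labels: the orange context's realized stop rate is 28/108 ≈ 0.259 and the
yellow one's 18/108 ≈ 0.167.

Block compositions are sampled as i.i.d. uniform draws from {9, 18, 27}
conditioned (by whole-sequence rejection) on summing exactly to the context
total. The conditioning matters: re-drawing only the overshooting block
skews the marginal toward 9 (≈0.40/0.31/0.28 for 108-trial contexts), while
the conditioned sampler gives ≈0.360/0.333/0.307 by exact enumeration —
near-equal frequencies under the exact-total constraint. Block order is
rejection-shuffled until no two adjacent blocks share a context; designs
with many blocks (scaled-up schedules) fall back to a constructive sampler
that picks the next context with probability proportional to remaining
blocks and forces any context holding more than half the remainder. A
single-context design skips the (vacuous) constraint. Trial kinds and
stimulus types are balanced at the context level and placed uniformly at
random within each context's blocks; picture identities are dealt from the
exact 12-per-picture multiset, so balance holds for every seed.

Onset convention: trial onset = cue onset; picture onset = trial onset +
750 ms; all schedule times are integer milliseconds.

## Race-model simulator

Subject behavior follows the independent horse-race model. The go process
finish time is ex-Gaussian — the standard RT model — with mean shifted
additively by `proactive_gain × p_context` (linear proactive slowing, which
is exactly the linearity the slope measure assumes) and optionally by a
poker-stimulus offset. The stop process latency is normal truncated at zero.
On a stop trial the subject responds iff the go process beats both the stop
process (G < SSD + S) and the deadline; SSD is measured from picture onset
(the signal is only audible while the picture is shown, hence the SSD clamp
at 0–1250 ms). Omission lapses (probability `p_miss_lapse`) and
categorization errors (`p_choice_error`) are independent Bernoulli events; a
trigger-failure probability exists as an extension point and defaults to 0.

Two SSD staircases per subject (neutral, poker) start at 800 ms, move
±25 ms (1-up/1-down) and are shared across the yellow/orange/red contexts.
This titrates the long-run respond probability to 0.50 for any overlapping
go/stop distributions.

Cohort defaults (the simulated study conditions): per-subject parameters are
drawn from group-level normals with control go_mu 760 ± 60 ms and poker
players 60 ms faster at equal true SSRT (200 ± 25 ms between subjects,
within-subject stop-latency SD 30 ms); go_sigma 60 ± 10 ms, go_tau
100 ± 20 ms; proactive gain 600 ± 150 ms per unit probability; lapse rate
0.05 and choice-error rate 0.02. These put pooled go RT near 950 ms,
failed-stop RT ≈ 45 ms faster than go RT, accuracy ≈ 98%, and context miss
rates rising from ≈0.06 (green) to ≈0.12 (red) — the behavioral regime the
analysis chain expects (accuracy above 96%, misses around 0.09–0.13 in the
stop contexts, SSRT estimates in the 160–210 ms range). An optional scalar
"neural covariate" is generated by a Gaussian copula against each subject's
realized proactive slope: slope ranks are mapped to normal scores and the
covariate drawn jointly normal at Pearson ρ = 2·sin(π·ρ_s/6), so the pair's
population Spearman correlation equals the target (default −0.47).

What the generator does *not* emulate: sequential (post-stop-trial) slowing,
RT autocorrelation and fatigue, context-specific SSD re-centering, strategic
waiting near the deadline, and any true coupling between neural activity and
behavior beyond the copula stand-in. Passing tests therefore certify the
schedule, the estimators and the inference machinery under the race model's
assumptions — not that real subjects satisfy those assumptions.

## Per-subject measures

* **Outlier filter.** Within each (context × stimulus) cell of responded go
  trials, RTs outside [Q25 − 1.5·IQR, Q75 + 1.5·IQR] are dropped before RT
  means and slopes. Quantiles interpolate linearly between order statistics
  (the numpy default); cells with fewer than 4 RTs pass unfiltered. The
  fences always contain the median; in adversarial configurations (zero
  IQR with two extreme tails) the rule can drop more than a quarter of a
  cell, though never half.
* **Proactive slope.** OLS slope of the four context mean RTs on nominal
  stop probability [0, 0.17, 0.25, 0.33], per stimulus type and pooled.
* **Integration-method SSRT.** Per stimulus type: pool go trials from the
  yellow/orange/red contexts (green carries no SSD and stays out),
  substitute omissions with the 1250 ms deadline, take the RT at 1-based
  rank ⌈p·N⌉ (capped at N) where p is that stimulus type's overall
  p[respond|signal], and subtract its mean SSD. The distribution is
  deliberately unfiltered — the miss-substitution rule presumes the full
  distribution. Choice-error RTs stay in.
* **Validity and exclusion.** Tracking is flagged healthy when pooled
  p[respond|signal] ∈ [0.35, 0.65]; race-model independence when mean
  failed-stop RT < mean go RT (both pooled over the stop contexts; reported
  as not evaluable without failed stops). Subjects responding on strictly
  more than 70% of stop trials are excluded before group analysis.

Known estimator bias under these study conditions: the integration SSRT
pools go RTs weighted by go counts (45:40:36 across yellow/orange/red) while
stop trials — and with them the staircase equilibrium and mean SSD — are
weighted 9:14:18 toward the slow red context. With a 600 ms/unit proactive
gain this mixture mismatch alone subtracts ≈14 ms (600 × 0.0235, the gap in
mean stop probability between the two weightings), and SSD oscillation plus
stop-latency variability contribute another ≈5 ms through quantile-function
curvature. The estimate for a 200 ms true stop latency therefore converges
to ≈181 ms, not 200 ms, no matter how many trials are simulated; it is
asymptotically unbiased only when contexts are exchangeable and noise is
small. This is a property of the estimator-plus-design combination, not of
the simulator, and it is consistent with empirical SSRT values in the
160–210 ms range reported for this paradigm.

## Group inference

The mixed (split-plot) repeated-measures ANOVA handles any number of fully
crossed within-subject factors and at most one between-subjects factor on
balanced complete data (no imputation; unbalanced input raises). Sums of
squares come from the classical marginal-means (Yates) decomposition;
error terms follow the split-plot convention — subjects-within-groups for
the between factor, effect × subjects-within-groups for each within effect
and its group interaction. Effect sizes are partial η² = SS_eff /
(SS_eff + SS_err). Degrees of freedom are textbook split-plot values;
published reports of this paradigm sometimes print other denominator df,
which are not reproduced. No sphericity correction is applied by default;
`fit(gg_correction=True)` adds Greenhouse–Geisser ε (from orthonormal
effect contrasts on the pooled within-group covariance) and corrected
p-values. The implementation is cross-checked in the test suite against a
brute-force projection oracle (nested OLS on dummy matrices), pingouin and
statsmodels on their overlapping designs.

Pairwise context comparisons are paired t-tests over all six pairs with
Bonferroni adjustment (zero-variance differences are reported as t = 0,
p = 1). Spearman correlations use average ranks for ties; p-values come
from the exact permutation distribution for n ≤ 9 and the t approximation
otherwise; Bonferroni multiplies by the number of tests and caps at 1. The
study-level model correlates a per-subject covariate with the proactive
slope, SSRT and p[respond|signal] (m = 3).

## Problem sizes and numerical choices

Long-run experiments scale the default design by an integer factor
(`scaled_design`), keeping block structure and picture balance exact:
staircase-convergence runs use ≥5,000 stop trials per staircase and
estimator-consistency runs ≈10,000. The ANOVA type-I-error calibration in
the test suite runs 2,000 null cohorts (identical groups, proactive gain 0,
8 subjects per group) on a reduced 72-trial design that preserves the
9/18/27 block structure — chosen so the calibration gives a stable rate at
a practical cost. Go trials are simulated vectorized; only stop trials are
walked sequentially (the staircase is the only sequential dependence).
Ex-Gaussian finish times are clamped at a positive floor (10⁻³ ms) and
truncated normals sampled by rejection. All randomness in a run descends
from one integer seed through a single `numpy` Generator, so outputs are
byte-identical across repeated invocations.

## Limitations

Estimates inherit the integration method's biases described above; the
ANOVA requires balanced complete data by design; the copula covariate is a
stand-in for a neural measurement and carries no mechanistic content; and
the exact-permutation Spearman p is limited to n ≤ 9 for cost reasons.
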