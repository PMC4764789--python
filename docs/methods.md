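# Methods

## The goal-setting model

The engine implements percentile shaping: a reinforcement criterion (the
daily step goal) placed at a chosen percentile of the subject's recent
performance distribution, so the criterion adapts as behavior changes.
Concretely, the `window_days` (default 9) most recent *measured* daily step
counts are ranked ascending and the goal is drawn uniformly on the
nearest-rank percentile range `[P_low, P_high]` (defaults 50 and 70). The
nearest-rank convention — `P_p = x_(ceil(p·n/100))`, a 1-based order
statistic — always returns an observed value and is exactly the rule the
property suite checks against a brute-force cumulative-rank scan.

The published description of the production system fixes the window length
(9 days), states the range sits "slightly above" the user's median, and
describes random selection within the range; it does not print the upper
percentile, the selection law, or the early-history compensation. The
package's choices, all surfaced in `GoalPolicy`:

* **Range P50–P70.** For n = 9 this uses the 5th and 7th order statistics,
  bracketing the 60th-percentile single criterion used in earlier adaptive-
  goal work while honoring "a range slightly above the median".
* **Uniform selection** within the range: the least-assuming law, and the
  observed day-to-day variability of goals is an emergent property, not a
  calibration target.
* **Early-history compensation.** Fewer than `min_history_days` (2) measured
  days → the fixed `floor_goal` (2000 steps); otherwise the available days
  are ranked as a shorter window and flagged `compensated` until a full
  window exists.
* **Rounding and floors.** Goals are rounded to `rounding_step` (10 steps;
  human-readable) and clamped to `floor_goal`. When the percentile range
  contains at least one multiple of the rounding step, the rounded draw is
  clamped onto those multiples so the goal stays inside the range; a range
  narrower than one step falls back to the nearest multiple of the draw.
* **Window membership.** Only treatment-phase measured days feed the window
  (no run-in data — live deployments have no pre-enrollment history), and
  zero-step days are excluded as non-wear artifacts: treating them as real
  zeros would collapse the goal after any non-wear day.
* **No goal cap** beyond the window maximum.

Randomness: each day's draw comes from an independent stream keyed by
(policy seed, participant id, calendar date), so a goal is a pure function
of the measured history before that date — truncating or extending the
series never changes earlier decisions, and any single day can be replayed
in isolation.

## Measurement rules

Wear time for 20-minute epoch data is the span from the start of the first
non-zero bin to the end of the last one (interior gaps count as wear; a
single active bin is 20 min). This is deliberately the trial's simple
first-to-last-activity estimate, not a gap-aware non-wear algorithm
(Choi/Troiano are out of scope). Valid day: wear ≥ 10 h (inclusive). Valid
assessment window: ≥ 4 valid days in 7 including a Saturday or Sunday;
missing calendar days count as invalid days, not errors. Assessment mean:
total steps on valid days / number of valid days. When epoch and daily data
coexist for a day, the epoch-derived values win (raw source) and a warning
is logged.

## Trial protocol

All participants share a protocol clock (staggered enrollment is not
modeled): 7-day run-in → 42-day treatment → 7-day follow-up window, with a
second 7-day retry window for participants whose first window fails the
wear criterion. Eligibility, baseline, and stratum (sedentary < 5000,
low-to-somewhat 5000–9999, active ≥ 10,000 steps/day) come from the run-in
window; only eligible participants are randomized. Randomization is blocked
1:1 within stratum (per-stratum arm counts differ by ≤ 1 for every seed;
simple coin-flip allocation would not reproduce the near-perfect balance a
real enrollment system produces). Follow-up summaries use the first *valid*
window even when both are valid. All flags are pure functions of records +
rule, so re-running the harness is idempotent.

## The behavioral simulator

Expected steps for participant *i* on study day *d*:

    mu_i(d) = b_i · dow(weekday) + A_i · 2^(−d/h) + s·d
              + drift_i · 1[post-run-in] + r_i · 1[intervention, post-run-in]
              + boost · 1[pursuing ∧ mu < goal]

realized as `max(0, Normal(mu, sigma_w))`, rounded to an integer. Parameter
defaults (per day unless noted):

| parameter | default | why |
|---|---|---|
| baseline b_i | stratum-truncated normals: sedentary N(3800, 950) on [1500, 4999], low N(6800, 1250) on [5000, 9999], active N(11000, 900) on [10000, 14000] | reproduces the per-stratum baseline means/SDs of the trial population |
| stratum mix | 0.536 / 0.449 / 0.015, largest-remainder allocation | yields exactly 142/119/4 at n = 265 |
| day-of-week dow() | (0.98, 1, 1, 1, 1.04, 1.08, 0.90) Mon–Sun, mean 1 | mild weekday structure; weekends lower for a workplace cohort |
| within-person SD sigma_w | 1800 steps | with the person-level terms below, change-score SDs land at ~1700–1900, matching the observed ~1824/1874 |
| reactivity A_i, half-life h | max(0, N(800, 500)), h = 5 d | a temporary measurement-reactivity boost that has essentially vanished by follow-up |
| secular slope s | −2.32 steps/day² | with reactivity decay, expected control change ≈ −661 steps/day (the observed control decline, read as reactivity wearing off plus a seasonal summer→fall decline) |
| drift_i | N(0, 1350), persistent post-baseline | slow lifestyle drift between baseline and follow-up; the main contributor to realistic change-score dispersion |
| response r_i | N(970, 800), intervention arm only | the configured treatment effect; 970 steps/day is the trial's observed between-arm difference |
| wear | N(14.4, 1.2) h; non-wear days (p = 0.08) wear ~ U(0, 2) h with proportionally scaled steps | valid-day wear mean 14.4 h and ~6.4 valid days per week |
| follow-up dropout | p = 0.15 (both follow-up windows unworn) | produces follow-up completion in the low-to-mid 80 % range |

Noise is a zero-clipped normal rather than a truncated normal or negative
binomial: at these means the clip probability is ~2 %, the induced bias
(tens of steps, nearly equal across arms) is far below the effects of
interest, and it keeps the day model a two-parameter object.

The intervention response is a direct additive term rather than being
routed through goal pursuit. A Bernoulli pursuit gate with a boost applied
only when the day's expectation sits below the goal is available
(`EffectProfile.goal_pursuit_prob` / `pursuit_boost`) as the mechanistic,
goal-coupled alternative, but because goals are themselves adaptive the
expected effect of that mechanism is not available in closed form; the
additive default makes the configured Δ exact in expectation, which is what
effect-recovery calibration needs. Control participants generate no
treatment-phase data (they are instructed not to wear the tracker between
baseline and follow-up); retry-window data are generated for everyone and
simply ignored when the first window is valid.

Treatment-arm days are generated interactively against the goal engine:
each day's goal is computed from the realized records strictly before that
day, so the no-look-ahead contract holds inside the simulator too.

**What the generator does not emulate:** weather/geolocation covariates,
social contagion between participants, autocorrelated within-person noise,
device measurement error, partial-sync data loss, or engagement channels
(email opens, site visits) — the engagement analysis accepts an optional
external event log instead. Treatment-phase wear adherence is governed by
the same non-wear probability as assessments, so simulated worn-day rates
run higher than the engagement levels a real cohort shows. Passing
calibration tests therefore demonstrates internal statistical consistency
of the pipeline under these study conditions, not fidelity to any real
cohort's raw step series.

## Outcome statistics

Change score = follow-up mean − baseline mean per participant; the primary
set requires a valid baseline and a valid follow-up assessment. The
between-arm test is Welch's t by default (pooled-variance optional — the
published analysis does not say which was used; both reproduce the printed
p-value bounds). Responders gained ≥ 1000 steps/day (inclusive), compared
by the uncorrected Pearson chi-square: only the uncorrected statistic
reproduces a p of .018 from responder counts 32/107 vs 18/110. Per-stratum
contrasts cover the sedentary and low-to-somewhat strata only (the active
stratum is too small to compare); the sensitivity analysis recomputes
follow-up means over *all* valid follow-up days across both windows,
dropping the 4-day/weekend requirement. Engagement: a worn day has > 100
steps; a goal is completed at steps ≥ goal (inclusive). Degenerate inputs
(identical arms, zero variance) return defined results (t = 0, p = 1)
rather than raising. P-values are exact tail probabilities; thresholds like
"< .001" are presentation-layer formatting. The repeated-measures
mixed-effects robustness model is intentionally not reimplemented —
`change_scores` exposes the per-participant data for standard tooling.

## Problem sizes and numerical choices

The calibration suite runs one full 265-participant trial for effect
recovery (estimate within 2 SE of the configured 970) and 200 null-effect
replicates at n = 265 for the type-I-error check (rejection rate 5 % ± 2 %),
with goal computation skipped in null replicates since goals cannot affect
behavior when the boost and response are zero (goal draws use separate
random streams, so this changes nothing else). Exhaustive percentile
validation covers every multiset window of lengths 1–9 over a 5-value grid
(2001 windows — exhaustive because the statistic depends only on the ranked
multiset). Property-based suites run 1000 derandomized cases each. The
end-to-end CLI determinism check uses a 40-participant cohort. All
randomness flows from named SeedSequence substreams of a single seed
(per-participant behavior, randomization, effect draws, per-day goals), so
modules replay independently and pipeline outputs are byte-identical at a
fixed seed.

## Known limitations

* The production system's exact percentile range, selection law, and
  early-history compensation are undocumented; `GoalPolicy` defaults are
  declared assumptions, all configurable.
* The simulator is calibrated to arm-level summary statistics only; no
  individual-level variance decomposition was available, so the split
  between within-person noise, drift, and response heterogeneity is a
  modeling choice.
* Wear-time estimation by first-to-last activity over-counts wear across
  long midday non-wear gaps, exactly as the span rule itself does.
* The type-I-error calibration is a finite-sample binomial check: a
  perfectly calibrated 5 % test lands in the 3–7 % band with ~86 %
  probability at 200 replicates.
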