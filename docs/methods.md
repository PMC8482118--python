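# Methods

## The task and its trial-level representation

The Sustained Attention to Response Task (SART) presents the digits 1–9 in
order, 23 times (207 presentations; 300 ms stimulus, 800 ms inter-stimulus
interval). Participants press for every digit except 3 and withhold on 3.
Pressing on a 3 is a *commission* error; not pressing on any other digit is
an *omission*. A perfect administration therefore contains 8 × 23 = 184
recorded reaction times and 23 correct withholds.

`sartkit` works at the level of the 9-digit *cycle* (23 per administration).
For each cycle it computes the mistake decomposition (omissions +
commissions, at most 9), the error fraction (mistakes / 9), and the mean RT
over *correct GO presses only* — commission RTs are recorded but never used.
A cycle with no correct press, or with a press whose RT was not recorded,
has no computable mean RT: it cannot be placed in the visualization
("unplottable") and is excluded from the threshold estimate below. The most
mistakes a plottable cycle can carry is 8, since one correct press is needed
to give the spot a vertical position.

## The bad-performance threshold

In the multimodal visualization every plottable cycle is a spot whose area
grows with the cycle error fraction. Pooling all plottable cycles of all
participants, a spot is *big* — the cycle is a *bad performance* — when its
size exceeds the pooled mean by more than two sample standard deviations:

    cutoff = mean(error_fraction) + 2 · sd(error_fraction)
    mistake_threshold = min { k ∈ 1..9 : k/9 > cutoff }   (10 if none)

The inequality is strict, matching "larger than 2 SD". On cohorts generated
with the default configuration the rule lands at 4 mistakes out of 9, the
value the validation study reports for its cohort.

Three per-participant predictors summarise the 23 cycles:
`bad_performances` (cycles with ≥ threshold mistakes), `total_mistakes`
(sum over all cycles) and `mistakes_in_good_performances` (sum over cycles
below threshold). The decomposition `total = in-good + in-bad` is exact.
Two policy switches exist because the source procedure is ambiguous:

* unplottable cycles count toward `bad_performances` when their mistake
  count reaches the threshold (a cycle with no press at all has 8 mistakes
  and is plainly a bad performance); `bad_perf_plottable_only=True`
  restores the stricter spots-only reading;
* the threshold is recomputed from the analysed dataset by default;
  `--threshold 4` (or `ThresholdResult.pinned(4)`) pins the published value
  for cross-dataset comparability.

`mean_rt_ms` / `sd_rt_ms` are taken over all recorded correct-GO RTs of the
whole task. No RT plausibility filter (e.g. anticipation cut-off) is
applied. The spot-size mapping (area linear in error fraction between
configurable bounds) and the light-brown→black colour ramp are presentation
conventions, not contracts.

## The visualization

Participants are columns ordered by increasing age; x is the integer rank,
not the age, so ticks marking 5-year bands are non-uniformly spaced (most
of the cohort is 50–65). Ties in age break stably by participant id. With
TUG stratification the low-TUG block (dark blue) precedes the high-TUG
block (light blue), age-ordered within each. Overlay curves show total
mistakes and baseline MMSE and TUG, the latter two multiplied by exactly 3
to be legible at the RT scale. The thresholded variant keeps only big spots
and restricts the overlays to participants with at least one of them.

## Outcomes and the model suite

Binary wave-1 → wave-3 outcomes: TUG decline (TUG₁ < 12 s and TUG₃ ≥ 12 s),
UGS decline (UGS₁ ≥ 100 cm/s and UGS₃ < 100 cm/s), new faller (falls₁ = 0
and falls₃ > 0), MMSE decline (drop ≥ 2 points). Flags are null when an
input is missing. Because each outcome is a transition from a normal
baseline, baseline-impaired rows (e.g. TUG₁ ≥ 12 s) are *excluded* from the
corresponding regression by default; `baseline_impaired="keep"` retains
them coded 0, the alternative reading of "and 0 otherwise". Cut-offs
(12 s, 100 cm/s, 2 points) are constants with overrides.

Each outcome is regressed on exactly one of the three SART predictors in
five nested logistic models: (1) predictor only; (2) + mean RT, SD RT;
(3) + age, sex, education; (4) + anxiety, depression, antihypertensives,
diabetes, smoking, drinking problem, IPAQ; (4a) + baseline UGS. Dummy
coding uses reference levels primary/none education, never-smoker, low
IPAQ, and no drinking problem with a separate don't-know indicator.
Complete cases only; no imputation; no multiple-testing correction across
the outcome × predictor grid (per-model α = 0.05).

Inference is maximum likelihood with Wald 95% CIs on the log-odds scale,
exponentiated to ORs, and two-sided Wald p-values — the default behaviour
of the statistical package the original analysis used. Separation and rank
deficiency raise errors naming the offending columns; there is no silent
penalisation. Adjusted models are screened for collinearity with pairwise
Spearman |ρ|; since no published cut-off exists the default pass limit is
0.7, configurable and always reported. Nonparametric comparisons use the
Wilcoxon signed-rank test (zero differences discarded; exact null for ≤ 25
untied differences, else normal approximation with continuity correction)
and the two-sided Mann–Whitney U test. Normality screening combines the
Lilliefors-corrected Kolmogorov–Smirnov test with Shapiro–Wilk; a vector
is "normal" only when both fail to reject at 5%. The per-group TUG "slope"
is the mean TUG₃ − TUG₁ divided by one wave interval (with two time points
the slope equals the mean difference).

## The synthetic cohort generator

Real two-wave cohort data of this kind are access-restricted, so the
generator produces raw streams and a paired clinical table with the
statistical structure the analysis assumes.

**Error model.** Each cycle is in one of three latent attention states:

* *focused* — independent per-presentation errors at low baseline rates
  (omission 0.001, commission 0.012 for a median participant at age 60);
* *distracted* (rate 0.085) — a short disengagement producing a burst of 3
  omissions: mass just below the bad-performance threshold;
* *lapse* (median rate 9 × 10⁻⁴) — a severe whole-cycle breakdown with every
  presentation erring independently at 0.78 (omissions dominate; the NO-GO
  is usually pressed).

State propensities shift on the log-odds scale with age (+0.055/year) and
with a standard-normal latent attention deficit (loadings 2.9 on lapses,
0.8 on distraction, 0.5 on baseline rates). The heavy lapse loading
concentrates bad performances in a small subgroup, reproducing the strongly
non-normal, over-dispersed predictor distributions and a monotone age
gradient in the share of participants with bad performances. A two-state
model (baseline + rare uniform lapses) cannot simultaneously deliver ~11
total mistakes per participant *and* a pooled mean + 2 SD cutoff between
3/9 and 4/9 — the achievable per-cycle variance is too small — which is why
the mid-severity distraction state exists.

**Calibration.** Defaults are calibrated so an n = 5000 cohort matches the
published wave-1 moments: total mistakes ≈ 12 (target 11.0 ± 2), mean RT
≈ 385 ms, within-person SD RT ≈ 73 ms, TUG ≈ 8.6 s, UGS ≈ 136 cm/s, MMSE
≈ 28.7, and the threshold rule lands at 4 mistakes in essentially every
seed. Two targets cannot be hit jointly with the others: the calibrated
bad-performance mean sits near 0.5 cycles/participant (published: 0.3) and
~15% of participants have at least one bad performance (published: 11.6%).
The per-cycle mistake composition is omission-dominated, whereas real SART
errors are commission-heavy; the printed moments constrain totals, not
composition. Passing tests therefore demonstrate the pipeline's arithmetic
and statistical behaviour, not that the generator is a faithful model of
real sustained-attention data.

**RTs.** Correct presses draw from a participant-level lognormal
(log-mean 5.90 ± 0.23 across participants, within-person log-SD 0.185
scattered by a further log-normal factor), plus 2 ms/year of age, floored
at 120 ms. Commissions receive an RT that nothing downstream uses.

**Missing data.** 1.7% of participants get 1–2 degraded cycles (24% of
them fully unresponsive cycles, the rest missing RTs on presses), emulating
the published missing-data pattern; severe lapse cycles can also produce
naturally unplottable cycles. Wave-3 attendance is 80% (attrition 0.20) and
baseline TUG/UGS/MMSE have small missing rates, so the merged analysis
sample is ~80% of wave 1, mirroring the published cohort structure.

**Outcomes.** Binary flags are drawn from logistic links whose
coefficients live in the configuration (defaults follow the published
fully adjusted ORs, e.g. 1.287 per bad performance for TUG decline, 1.114
for new faller, with age effects on every outcome), using the
bad-performance count at the pinned threshold 4. The continuous wave-3
values are then constructed to agree with the drawn flags: TUG₃ starts as
TUG₁ + group increment + noise — 0.871 s for participants without bad
performances, 1.512 s with — and is nudged across/away from the 12 s
boundary to match the flag. This keeps the true OR of the bad-performance
count a known constant (enabling exact parameter-recovery and null-
calibration experiments) while preserving the steeper mean TUG increment
in the bad-performance group. UGS, falls and MMSE follow the same pattern
at their own boundaries.

**Seeding.** One master seed; profile, outcome and per-participant stream
substreams are spawned deterministically, so cohorts are bit-reproducible
and a single participant's stream can be regenerated in isolation.

## Problem sizes used in the test suite

Fast unit and property tests run on constructed streams and cohorts of a
few hundred. The end-to-end studies use: threshold recovery at n = 5000
over 10 seeds; OR recovery at n = 4000 over 200 replicates (true OR 1.30;
mean estimate within [1.25, 1.35], CI coverage within [0.90, 0.98]); null
calibration at n = 1200 over 500 replicates (KS uniformity at α = 0.01)
plus 1000-replicate size checks of the rank tests; oracle equivalence on
1000 random instances each. The whole suite runs in a few minutes on one
core.

## Known limitations

* The generator's bad-performance moments overshoot the published values
  (see Calibration) and its error composition is omission-dominated.
* Covariates are mutually independent given age; real cohorts correlate
  education, activity, smoking and age.
* No survey weights, no attrition mechanism related to health, no
  healthy-participant selection effect — merged-sample analyses are
  missing-completely-at-random.
* Wald inference only; no Firth-type fallback for separated designs (they
  fail loudly instead).
* The 12 s TUG cut-off variant at 14 s and frailty indices are out of
  scope beyond the config override.
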