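# Methods

This note records the model behind the package, the defaults and the
reasoning for choices the method's description leaves open.

## The co-calibration model

The object of inference is the monotone association between a
questionnaire-derived variable (an item, sub-score, or score with a
recall period) and a wearable-derived behaviour variable summarised
over a multi-day interval that *precedes* the answer. Because neither
side is on an interval scale — item codes are ordinal, wearable
variables are skewed and partly compositional — association is
measured by the Spearman rank correlation, and "detected" means the
95 % confidence interval of rS keeps its sign. No multiple-comparison
adjustment is applied: the method is exploratory by design, and its
outputs (counts and contours of strong correlations) are screening
devices for later confirmatory designs, not hypothesis tests.

### Wearable processing

* **Valid day**: ≥ 21 h of device wear (`min_wear_hours`, inclusive).
  Days below the threshold are excluded from every aggregate, never
  imputed.
* **Aggregate interval**: a window of 7, 14, 21, 28, 60, 90 or 120
  consecutive calendar days; it qualifies when ≥ 70 % of its days are
  valid (`min_valid_fraction`, inclusive). Unmonitored calendar days
  count against the fraction.
* **Absolute amount**: per-interval median of daily values. Cumulative
  variables (sedentary+light, light+fair, fair+vigorous) and the total
  active duration (light+fair+vigorous) are formed per day *before*
  the median — the median of sums is not the sum of medians, and the
  per-day-first order is pinned by test. Heart rate on low-wear days
  is absent, never zero (zero bpm is a sentinel, not a measurement).
* **Relative amount**: each day's (sedentary, light, fair, vigorous[,
  sleep]) minutes form a composition; zeros are replaced by a 1-minute
  pseudo-duration with multiplicative rescaling so the day total is
  preserved, then the centred log-ratio is taken. The day's own total
  is the closure denominator — CLR is scale-invariant, so this choice
  is mathematically immaterial, but it keeps partial-wear days
  well-defined. The interval aggregate is the componentwise arithmetic
  mean of daily CLR vectors, which equals the CLR of the geometric-mean
  composition exactly (tested to 1e−9); every relative vector sums to
  zero.

### Alignment

For an administration on day *t*, duration *d* and leeway *L*, the
candidate interval ends scan *t, t−1, …, t−L*; the first qualifying
end (the one closest to the administration) is paired. Data strictly
precede the self-report — the method correlates recalled state with
preceding behaviour, so future wearable data never enter. At most one
observation survives per participant and wave (the latest
administration), guarding against diligent responders dominating the
sample. Observation sets below `min_observations = 10` are discarded.
Sample size per grid cell is non-decreasing in leeway by construction.

### Correlation and significance

rS is the Pearson correlation of mid-ranks (tie-aware; delegated to
`scipy.stats.spearmanr`, with a brute-force recomputation as the test
oracle). The CI uses the Fisher z-transform with SE 1/√(n−3) — the
description of the method states the sign rule but not the CI
construction, so the choice is isolated in one function and can be
swapped (e.g. for a bootstrap). For n < 4 the CI is undefined and the
result is non-significant; a constant margin yields no result. |rS|
within 1e−12 of 1 is snapped to ±1 with a degenerate CI.

### Pattern metrics

* **Total** counts, per questionnaire variable and health group, the
  significant best correlations with |rS| ≥ 0.5 in each wearable
  family. Thresholds are interpreted on |rS|: strong negative
  correlations count (published summaries display −0.8 entries as
  strong).
* **Contour** orders the processed family as (sedentary,
  sedentary+light, light, light+fair, fair, fair+vigorous, vigorous)
  — cumulative variables sit between their constituents — and the CLR
  families as (sedentary, light, fair, vigorous); sleep, active and
  raw variables have no intensity ordering. For each significant
  centre with |rS| ≥ 0.8, the metric counts contiguous same-sign
  significant neighbours downward and upward. When several adjacent
  variables are all strong, each is its own centre. In reports a
  present-but-non-qualifying neighbour renders as "×" and an absent
  variable as blank.
* Best-cell ties break toward smaller duration, then smaller leeway,
  then larger n (prefer the tighter recall match).

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes,
not the physiology behind it. Defaults describe the emulated study:
39 participants (healthy:diseased 28:11, Bernoulli-assigned), two
countries, 730 monitored days from 2017-09-01, three answer waves
(2018-06-15, 2019-01-15, 2019-07-15) with 10 % administration
missingness and 10 % within-wave duplicate answers minutes apart.

* **Wear time**: a mixture of full-wear days (probability 0.8, uniform
  21.5–24 h) and short-wear days (uniform 2–20 h), exercising the
  valid-day filter with realistic interval-qualification failures.
* **Composition**: logistic-normal around a base of ln(700, 200, 30,
  10, 420) minutes (sedentary, light, fair, vigorous, sleep), daily
  log-noise SD 0.3, scaled to the day's wear minutes — so component
  minutes always close to wear time and the compositional invariants
  hold by construction. Steps and energy are monotone in (weighted)
  active minutes with multiplicative noise; heart rate is absent below
  1 h of wear.
* **Planted links**: to target Spearman ρ between a questionnaire item
  and a wearable variable, a participant-level behaviour latent *b*
  shifts the targeted log-composition component (0.8 per unit), and
  the item's trait is t = r·b + √(1−r²)ε with r = 2·sin(πρ/6), the
  exact Gaussian-copula rank-correlation mapping. The trait *is* the
  planted item's latent — answer noise for planted items lives inside
  the copula, so the target survives the deterministic item coding up
  to discretisation (≈ 0.015 in rS for a 7-level item). Unplanted
  items perturb a generic wellbeing latent with answer-noise SD 0.7.
* **Adjacent-intensity blocks** (`sample_intensity_block`) draw k
  intensity variables sharing one behaviour latent, each at target ρ,
  with exchangeable residual correlation −1/k — the closure structure
  of a CLR family (an m-part composition's CLR components correlate at
  −1/(m−1); k adjacent intensities sit inside a (k+1)-part family).

What passing tests on this generator do **not** show: realism of the
marginal distributions (no circadian or seasonal structure, no
device-specific error spectra), behaviour change over waves (latents
are per-participant constants), or informative missingness (wear and
answer missingness are independent of state).

## Test and simulation sizes

Recovery of planted links is checked at ~100 *independent* aligned
pairs: 112 participants with a single answer wave, because the planted
trait is one scalar per participant and repeated waves would duplicate
rather than add information. The recovery check averages the Fisher-z
estimates of five replicate cohorts and requires the mean within the
single-run 2-Monte-Carlo-SE band — a test of systematic mis-recovery
that tolerates the ~5 % seed-level noise any single 2σ draw carries.
The contour-recovery rate for a planted three-intensity block at
ρ = 0.8 and n = 50 has a true value of ≈ 0.80 under the closure
design (the 0.8 strong threshold equals the planted value, so each
variable exceeds it with probability just under ½, and the three
estimates are necessarily dependent through the shared trait); a
200-replicate estimate of that rate therefore hovers around 0.80 with
binomial SE ≈ 0.028.

Null calibration of the CI-sign rule uses 1000 independent pairs at
n = 30 (observed false-positive rate ≈ 4–5 % at the nominal 5 %).
Pipeline demonstrations use 10–20 participants and reduced grids to
keep the suite fast; the statistics do not depend on these sizes.

## Known limitations

* The Fisher-z CI is an approximation for Spearman; at very small n it
  is conservative relative to exact permutation bounds.
* Categorical scores enter correlations through ordered integer codes;
  with only 2–3 levels their rank correlations are coarse.
* The GADS answer coding is configurable (binary default, 0–4 Likert)
  because administered variants differ; scores are not comparable
  across codings.
* The Self-MNA configuration emits the five declared screening items
  (0–12 points) with the published cut-offs; variants with six items
  rescale to 0–14.
* The generator's planted associations are constant per participant;
  within-person longitudinal co-variation is not modelled and the
  pipeline's wave-level sensitivity is accordingly untested here.
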