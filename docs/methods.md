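# Methods

## The generative model

Daily affect ratings are modelled as draws from a Gaussian whose mean
drifts: y_t ~ N(mu_t, SD_t²), mu_t = mu_{t-1} + N(0, vmu_{t-1}²). The two
scale processes evolve as Gaussian random walks on the log scale,
log vmu_t = log vmu_{t-1} + N(0, kmu²) and log SD_t = log SD_{t-1} +
N(0, vsd²), with kmu and vsd static per subject. Log-space walks guarantee
positivity and give scale-free dynamics; vmu_t is parameterized as the SD
(not variance) of the mean's innovation so that volatility and noise share
rating units and can be compared directly. The innovation of mu_t uses the
volatility *before* the step, which keeps one-step-ahead prediction causal.

Emitted ratings are clipped to the scale bounds (the simplest mechanism
consistent with bounded ratings). The latent mean *reflects* at the bounds,
implemented exactly as folding of the free walk. Without reflection, a
free random walk escapes the scale on realistic series lengths (roughly
half of 360-day simulations at volatility 0.05 saturate at an edge, after
which every rating clips and the series carries no information) — a
behavior no plausible affect diary shows. Tests that exercise the pure
random walk pass effectively infinite bounds.

Regime-schedule simulation (piecewise-constant volatility/noise levels
overriding the log walks) reproduces the benchmark scenario used to
demonstrate the filter: 360 days on [0, 1], volatility high (0.05) on days
1-120 and 301-360 and low (0.005) on 121-300, noise high (0.10) on days
61-120 and 241-360 and low (0.02) elsewhere, initial mean 0.5. The levels
are unpublished; these defaults are stored in one place
(`generative.DEMO_LEVELS`) and overridable.

## The filter

Inference is by dense grid filtering over the joint
(mu, log vmu, log SD, kmu, vsd) — chosen over particle filtering because it
is deterministic, admits an exact small-instance oracle, and is cheap at
diary scale. The static rates are inferred, not fixed. Per calendar day the
joint is pushed through the model dynamics (three conditional Gaussian
convolutions, each row-normalized after discretization so no mass leaks off
the grid edges) and, if the day was rated, reweighted by the observation
likelihood. Missing days advance the dynamics by exactly one predict step —
no interpolation or extrapolation. Where several ratings share a day, only
the first is assimilated.

**Observation likelihood.** Each mu cell is scored by the Gaussian
probability mass inside the cell, Phi((upper−y)/SD) − Phi((lower−y)/SD),
not the density at the midpoint. The two coincide when SD is large against
the grid spacing; when SD is smaller than the spacing the midpoint rule
aliases observation noise into apparent mean movement, which corrupts the
volatility/noise attribution (regime-segment orderings recovered in ~5/20
seeds with midpoint densities, 20/20 with integrated masses).

**Default grid.** mu: 25 points spanning the rating bounds ±10% of the
range; log vmu and log SD: 15 points each spanning 0.001-0.5 scale ranges;
kmu and vsd: 7 log-spaced points spanning 0.01-0.5 per day. All priors
uniform over the grid and configurable. A rating outside the mu grid is
clamped with a warning; if every cell's posterior mass underflows to zero
the filter raises an explicit error suggesting a wider grid rather than
renormalizing garbage.

**Pipeline grid.** Cohort/trial endpoint estimation uses a documented
preset (21 × 13 × 13 mu/log-scale points, rates capped at 0.2/day, 5
points). Endpoint expectations are insensitive to resolution (checked up to
25×25×25), and a rate of 0.5/day — volatility changing by ×1.65 per day —
is far faster than mood dynamics over 40-60-day diaries; admitting it only
injects day-to-day jitter into single-day endpoints (change-score SD 0.035
→ 0.029 against a known-rates floor of 0.027).

**Numerics.** The batched engine processes series in cache-sized chunks
with preallocated buffers; each convolution is one BLAS matrix product.
Posterior cells below 1e-280 are flushed to exact zero (total flushed mass
< 1e-250 per day): the posterior concentrates quickly and subnormal
arithmetic otherwise slows BLAS several-fold. Batched results match the
single-step public operations to ~1e-16 and the exhaustive-enumeration
oracle cell-wise to < 1e-8; with the scale dimensions pinned, posterior
means of mu match the closed-form local-level Kalman recursion to
RMSE ≤ 0.01 on 50-day series.

## Classic metrics

Mean and SD (ddof=1), RMSSD, mean Teager–Kaiser energy
(Psi_t = y_t² − y_{t−1}·y_{t+1}), sample entropy and the AR(1) inertia fit
(OLS of y_t on y_{t−1} with intercept; residual SD with denominator
n−2). Difference-based metrics use only pairs/triples on consecutive
observed days — gaps are never bridged, so missingness is not read as
variability. "Entropy" is sample entropy with embedding m=2 and tolerance
r = 0.2 × the population SD of the longest consecutive run (the estimator
used by earlier diary analyses is not identified; the choice is
configurable). If no template pair matches, the explicit sentinel
`ENTROPY_UNDEFINED` (+inf) is returned; a numerically constant run has
entropy 0 by convention. Simulations in the test-suite confirm the known
limitation that motivates the filter: raising either volatility or noise
raises SD, RMSSD and TKEO — the classic metrics do not separate the causes.

## Synthetic cohort and trial

The diary datasets this pipeline targets are not publicly depositable, so
the package generates stand-ins with the hypothesized structure, plus the
true generative parameters per subject for recovery testing.

**Cohort** (six descriptors — anxious, elated, sad, angry, irritable,
energetic — on a 1-7 Likert scale, 60+ days): per subject and valence,
vmu0 and sd0 are drawn log-normally from group presets on a latent 0-1
scale; the day's latent value (the valence-level observation) is mapped to
each item by adding N(0, 0.05) jitter, affine-scaling, rounding and
clipping; whole days go missing i.i.d. (default 15%). Group presets: BD
volatility median 0.032 (≈3× control's 0.010), BPD noise median 0.110
(≈1.7× BD's 0.065, ≈2.4× control's 0.045), BPD negative-affect baseline
raised (0.45 vs control 0.18), BD partly lithium-flagged (43%), BPD more
often female and with lower educational attainment. Between-subject
log-normal sigma 0.4 (volatility) / 0.3 (noise). Magnitudes are chosen for
clear qualitative recovery of the BD-volatility / BPD-noise signature, not
to match unpublished effect sizes. The positive/negative item split
(elated+energetic vs the rest) follows item semantics and is configurable.

**Trial** (ten PANAS items on a 1-5 scale; 14-day run-in + 28 treatment
days; 10% daily missingness): participants are BD patients, so the BD
preset medians are reused with a tighter between-subject sigma (0.25),
reflecting the narrower trial population. From the first post-randomization
day the lithium arm's positive-affect volatility is multiplied by a factor
(default 2.0); placebo and negative affect are untouched, so a factor of 1
is an exact null.

What the generators do **not** emulate: circadian/weekly structure,
event-driven affect responses, response-style biases, dropout-by-severity,
or item-specific factor structure. Passing tests therefore show that the
pipeline recovers the intended signal under the assumed generative process
with Likert discretization and day-level missingness — not that real
diaries satisfy those assumptions.

## Analysis pipeline

1. Composite positive/negative scores = mean of the valence's items; a day
   missing any constituent item is missing (no partial averaging).
2. Inclusion: ≥ 10 observed composite ratings per valence.
3. Window: the contiguous 50-day stretch with fewest missing days
   (earliest start on ties); shorter series are used whole with a warning.
4. Composites are normalized to the latent 0-1 scale and filtered; the
   endpoints are the posterior expectations on the window's final day.
5. Volatility/noise endpoints are Box-Cox transformed (λ = 0.2; they are
   right-skewed).
6. Mixed-design RM-ANOVA with within factors cause (volatility, noise) ×
   valence (positive, negative), between factor group, covariates age, sex
   (binary), education (ordinal 1-5); rows with missing covariates are
   dropped. Implementation: each within effect is an orthogonal per-subject
   contrast analyzed by OLS with sum-coded group and centered covariates —
   for two-level within factors this *is* the classical univariate
   mixed-design ANOVA (an explicit sums-of-squares oracle in the tests
   confirms equality), and sphericity is not an issue. Post hoc pairwise
   group contrasts on the volatility and noise scores multiply p by three
   (Bonferroni, p_bonf = min(1, 3p)). Mean and SD are analyzed separately
   with valence as the only within factor (they are not causes of
   variability).
7. Trial: the filter runs over the full diary; "end of run-in" and "end of
   treatment" are the estimates on the last run-in day and last treatment
   day; participants with no rating on an endpoint day (estimate would be
   prediction-only) are excluded with logging. Change scores (end minus
   run-in-end) are analyzed untransformed by the same contrast RM-ANOVA
   with between factor arm, plus two-sided two-sample t tests per change
   score.
8. `lithium_factor_anova` adds cohort lithium status as an *additive*
   between-subject factor (score ~ group + lithium + covariates, per
   valence x cause): additive rather than crossed with group, because only
   the BD group contains treated participants. Covariates that are
   constant in the analyzed rows (e.g. sex after a female-only `--subset`)
   are dropped automatically with a log message.

## Problem sizes used in the test-suite

Chosen as the package's own simulation design: regime scenario 20 seeds ×
360 days; oracle grids ≤ 3 points/dimension × 5 steps; Kalman equivalence
20 × 50-day series; parameter recovery 40 subjects × 50 days; cohort
recovery 10 seeds × 30 subjects/group × 60 days; full-size default cohort
(51/33/51) once for truth-record recovery; trial specificity 10 seeds ×
20/arm; trial type-I calibration 40 replicates × 12/arm and cohort null
calibration 20 replicate cohorts × 10/group (type-I error does not depend
on n, so the null replicates use small groups).

## Known limitations

* The day-50 volatility endpoint of a single subject carries substantial
  posterior uncertainty; group inferences are reliable, individual
  endpoints noisy (change-score SD ≈ 0.03 on the 0-1 scale even with the
  generative rates known). Consequently the simulated lithium trial at
  n = 20/arm and a ×2 volatility effect has ≈55% power per replicate for
  the positive-volatility t test — comparable to the marginal effect sizes
  such trials report.
* Grid filtering costs memory/time exponential in the number of state
  dimensions; the five-dimensional joint is near the practical ceiling.
* The filter is causal (filtering, not smoothing): estimates early in a
  series reflect burn-in from the uniform prior and stabilize after
  roughly 10-20 observations.
* Day indexing is integer study days; irregular intra-day sampling beyond
  "first rating of the day" and continuous-time gaps are out of scope, as
  is hierarchical pooling across participants.
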