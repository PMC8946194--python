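# Methods

## The problem

In prospective duration estimation, a participant knows in advance that a
verbal estimate of elapsed time will be required. Concurrent cognitive load
(attentional-gate accounts) shortens subjective duration, while attending
only to time lengthens it; gross motor activity (walking) interacts with
both. The data are trial-level records: participant, motor condition
(sitting/walking), cognitive task (look, read, solve_simple, solve_hard),
nominal interval T ∈ {15, 30, 60, 90, 120} s, the actual integer duration d
drawn from a ±10% jitter window around T, and the verbal estimate e > 0.

The quantity of interest is the estimation bias Δ = e − d (positive =
overestimation) and its dependence on duration, plus the estimate's
dispersion as a function of duration (scalar timing: constant coefficient of
variation).

## Experiment design generator

Per participant and motor condition the design holds 4 tasks × 5 intervals ×
10 repetitions = 200 trials, arranged in 20 blocks of 10 where every nominal
interval appears exactly twice per block (so blocks have comparable
duration); the first 10 blocks are tagged session 1, the rest session 2.
Tasks are assigned to trials at random subject to the 10-per-cell quota, so
blocks mix tasks. Actual durations are uniform over the integer window
[⌊0.9T⌋, ⌈1.1T⌉] — boundary rounded outward, giving supports of size 5, 7,
13, 19 and 25 (e.g. 13…17 s for the 15 s interval). The treadmill speed
schedule (1.4–3.0 km/h, steps of 0.4–1.6 km/h every 20–40 s) is generated as
metadata only and never feeds back into the estimates.

## Generative models

**Linear clock (default).** e = α + g·d + ε with ε zero-mean and
SD(ε) = cv·(α + g·d), so the coefficient of variation of the estimate is
constant in duration (scalar property) and the per-bin RMSE grows linearly.
Defaults for (α, g) per task × condition cell come from the published
group-level bias fits (`prostime.reference.BIAS_FIT_REFERENCE`), e.g.
look/sitting α = 6.4 s, g = 1.005; solve_hard/walking α = 1.8 s, g = 0.6.
The default cv is 0.2, the approximate level of the published RMSE-vs-
duration slopes (0.14–0.23). The noise law is Gaussian by default with the
estimate floored at 1 s; a log-normal mode with the same cv is provided
because raw verbal estimates are typically right-skewed, but the published
material does not establish the direction of skew, so the symmetric law is
the default. A contamination component (rate 0.02, noise-SD multiplier 5) is
an artifact addition — real filtered tails must come from somewhere for the
outlier filter to be exercised; it is not a claim about the mechanism.

**Pacemaker–accumulator.** Per trial the clock rate is λ_t = λ(1 + η), η
zero-mean Gaussian (SD σ_gain, truncated positive); the attentional gate
passes pulses with probability p, the accumulator count is
N ~ Poisson(p·λ_t·d), and the readout divides by a calibration gate:
e = N/(p_ref·λ). For λ·d large the Poisson term vanishes and CV(e) → σ_gain,
again the scalar property. The calibration gate is not observable in
behavioural data; the default sets p_ref to the read task's gate (sitting
0.85, walking 0.80) so that reading is near-veridical, and scales the other
gates by their caption gains relative to read. This mode demonstrates that
the analysis chain recovers gate-ratio effects from a mechanistic data
source; it is not parameter-matched to the caption intercepts (a pure gate
model has no additive offset).

**Performance and covariates.** Math-task correctness is Bernoulli and
response time log-normal (means from the published performance summaries;
rt_cv = 0.4 chosen as a typical response-time dispersion). Fatigue and
tiredness follow linear per-block latent trends (slopes 0.01/0.15 and
0.13/0.16 per block for sitting/walking) reported on a rounded, clipped 1–7
Likert scale; body temperature has zero slope. These exist so the control
regressions are testable.

## Statistical chain

1. **Filtering.** For each task × condition × interval cell, the
   Hodges–Lehmann pseudomedian (median of all Walsh averages, self-pairs
   included) locates the estimate distribution; values strictly more than
   k = 3 raw-sample SDs (n−1 denominator) from it are removed in a single
   pass — the bounds are computed once from the unfiltered sample and not
   iterated, the most conservative reading of a "3 SD from the pseudomedian"
   rule. Boundary values are kept. The filter runs on the estimates (the raw
   distributions), and the bias rows inherit the mask.
2. **Bootstrap-through-filter.** Where a variance of a filtered statistic is
   needed, the raw sample is resampled with replacement (default B = 1000,
   seeded), the filter re-applied inside each replicate, and the statistic's
   SE taken as the SD of replicates. Degenerate replicates (< 2 survivors)
   are redrawn and counted.
3. **Binning.** Filtered biases are averaged over 2-s bins anchored at each
   jitter-window minimum (final odd bin holds one duration); 37 bins per
   task × condition for the default design. Bins with fewer than 2 trials
   are dropped with a log entry.
4. **Weighted line fits.** Per-bin mean bias is regressed on bin-centre
   duration with weights 1/SE²; parameter covariance comes from the weighted
   normal equations with the SEs treated as known, and
   χ² = Σ((y − ŷ)/SE)² is a goodness-of-fit statistic on n_bins − n_params
   degrees of freedom (35 for the default two-parameter fit).
5. **RMSE and CV.** Per-bin RMSE (dispersion about the bin mean — a
   *variability* measure; an about-truth variant is available behind
   `rmse_about="truth"`) is fitted two-parameter against duration, and
   one-parameter through the origin against the per-bin mean estimate; the
   through-origin slope is the coefficient of variation, whose constancy
   across tasks is the scalar-timing diagnostic. RMSE fit weights use
   SE(RMSE) ≈ SD_pooled/√(2(n−1)).
6. **Tests.** Per-cell biases are averaged per participant and tested
   against zero with a one-sample Wilcoxon signed-rank test — exact by full
   sign-assignment distribution for effective n ≤ 25 (computed by integer
   convolution over doubled ranks, identical to 2ⁿ enumeration), otherwise a
   tie-corrected, continuity-corrected normal approximation. Families of 20
   cells per motor condition are Bonferroni-adjusted. Slopes are compared
   with z = (b₁ − b₂)/√(se₁² + se₂²). Covariate-vs-block controls use OLS
   with t = b/SE(b) on n − 2 df.
7. **Percent effects.** Motor effect per interval = (mean estimate walking −
   sitting)/T in the look task; cognitive effect = (mean estimate look −
   solve)/T in the sitting condition, per solve task and combined. From the
   published group means these give a maximum motor effect of ≈ 17% at 15 s,
   mean ≈ 8%, and cognitive effects up to ≈ 61%.

## Numerical choices and calibration

* **SE of the per-bin mean (fit weights).** The default pools the within-bin
  variance across the bins of the same nominal-interval cell
  (SE = SD_pooled/√n_bin). Within a ±10% window the scalar property keeps
  the trial-level SD nearly constant, so pooling is unbiased there, and it
  removes the small-sample inflation of a per-bin SD: with ~12 trials per
  bin, per-bin SDs push the mean χ² to ≈ 41 against 35 df (the (n−1)/(n−3)
  effect) and make the parameter SEs anti-conservative, which a 50-cohort
  simulation confirmed (joint 2-SE coverage 87% per-bin vs 92% pooled, mean
  χ² ≈ 36). The per-bin variant remains available
  (`make_bins(se_method="per_bin")`).
* **RMSE fit weights** use the pooled scale for the same reason: weighting a
  bin's RMSE by its own noisy RMSE correlates weight with response and
  overdisperses the CV slope (observed z-test false-positive rate ~15%
  instead of 5%).
* **Zero-SE bins** get the smallest positive SE in the fit; if *all* SEs are
  zero (noiseless data) the fit falls back to equal weights.
* **Degenerate inputs:** single-value cells pass the filter unchanged;
  all-zero Wilcoxon differences report p = 1 with V = n(n+1)/4 and an
  "all-zero" flag; a perfect non-flat block trend reports t = ±∞, a flat one
  t = 0.
* **Determinism:** every random stage takes a seed; the pipeline derives
  child seeds (< 2³¹) from one master seed, and identical configs + seeds
  reproduce byte-identical reports.

## What the synthetic data do and do not show

The generators reproduce the design's counting structure, task/condition-
dependent linear bias, scalar variability, heavy tails (via contamination or
the log-normal mode), math-task performance levels and covariate block
trends. They do **not** model sequential effects (central-tendency pull,
block-order drift in the estimates), between-participant heterogeneity in
(α, g, cv) beyond sampling noise, response rounding to salient values
(10 s, 30 s, 1 min), or any mechanistic link between walking kinematics and
the clock. Passing tests therefore validate the *analysis chain* under the
stated assumptions, not conclusions about real behaviour.

## Problem sizes used in tests

End-to-end calibration checks use the study scale (16 participants × 2
conditions × 200 trials) across 50 seeded cohorts for parameter recovery, 20
for the scalar-timing null, and 10 for the false-positive control; oracle
equivalence checks (Walsh-average enumeration, 2ⁿ Wilcoxon enumeration,
normal-equation fits) run on samples up to n = 200. The full suite completes
in well under a minute of pure computation for the statistical modules plus
a few seconds per simulated cohort.

## Known limitations

* The published per-interval group means are a coarse surrogate for the
  original 2-s binned trial-level fits; refitting them reproduces the
  published slopes only to ~0.02–0.04 s/s.
* The mixed-effects model, repeated-measures ANOVA and normality screening
  that a full study analysis would add are deliberately out of scope; the
  report leaves the per-cell summaries and trial tables from which standard
  packages can fit them.
* The ingest schema is this package's own; mapping layers for external
  deposits are left as stubs.
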