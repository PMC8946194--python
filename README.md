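# prostime

Analysis tools for **prospective verbal time estimation under dual-task
load**: how well people judge elapsed intervals of 13–132 s while they look
at a screen, read aloud, or solve easy/hard mental sums — sitting or walking
on a treadmill.

The package is aimed at researchers analysing trial-level verbal-estimation
data (or planning such experiments via simulation). It provides:

* **Synthetic experiments** (`prostime.synthetic_data`): a factorial design
  generator (16 participants × 2 motor conditions × 4 tasks × 5 jittered
  intervals × 10 reps, blocks of 10 containing every interval twice) and two
  interchangeable generative models for the verbal estimate *e* of a true
  duration *d*:
  - a descriptive linear clock, *e = α + g·d + ε* with
    SD(ε) = cv·(α + g·d) — constant coefficient of variation, the *scalar
    property* — plus optional outlier contamination;
  - a mechanistic pacemaker–accumulator with an attentional gate: pulses at
    rate λ pass the gate with probability *p*, accumulate as a Poisson
    count *N*, and are read out as *e = N/(p_ref·λ)*.
* **Robust statistics** (`prostime.robust_stats`): Hodges–Lehmann
  pseudomedian, single-pass pseudomedian ± 3 SD outlier filtering, bootstrap
  variance *through the filtering stage*, exact/tie-corrected one-sample
  Wilcoxon signed-rank tests, Bonferroni adjustment, slope z-tests, and
  block-trend OLS controls.
* **Timing analysis** (`prostime.timing_analysis`): per-trial estimation
  bias Δ = e − d, 2-s binning over each interval's integer jitter window
  (37 bins for the default design), weighted straight-line fits with χ²
  goodness of fit (df = 35 for two-parameter fits), RMSE-vs-duration fits,
  the through-origin RMSE-vs-estimate slope as a coefficient of variation
  (CV), per-cell accuracy tests and percent motor/cognitive effect
  summaries.
* **A reproducible pipeline and CLI** (`prostime.pipeline_cli`):
  `simulate → filter → bin → fit → test → report`, fully determined by a
  JSON config plus a seed.

## Worked example

```python
import prostime as pt

report = pt.run_pipeline(pt.PipelineConfig(seed=17, with_covariates=False,
                                           with_performance=False))
fit = report["bias_fits"]["solve_hard:sitting"]
print(f"slope     = {fit['slope']:+.3f} +/- {fit['slope_se']:.3f}")
print(f"intercept = {fit['intercept']:+.2f} +/- {fit['intercept_se']:.2f}")
print(f"chi2({fit['df']}) = {fit['chi2']:.1f}")
cv = report["cv_estimates"]["solve_hard:sitting"]
print(f"cv        = {cv['cv']:.3f} +/- {cv['se']:.3f}")
```

prints

```
slope     = -0.306 +/- 0.009
intercept = +1.29 +/- 0.25
chi2(35) = 30.5
cv        = 0.205 +/- 0.005
```

The simulated hard-sum cohort underestimates durations more and more as the
interval grows (about −0.31 s of bias per second of duration, recovering the
generating slope of −0.3 within its standard error), starts from a small
positive offset (≈ 1.3 s, generating value 1.2 s), fits a straight line well
(χ² close to its 35 degrees of freedom), and shows a relative uncertainty of
≈ 0.2 — the configured coefficient of variation, i.e. the scalar property.

The same thing from the shell:

```bash
prostime simulate --seed 2 --out runs/sim
prostime analyze --in runs/sim/trials.csv --covariates runs/sim/covariates.csv \
                 --seed 2 --out runs/analysis
prostime report --run runs/analysis
```

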