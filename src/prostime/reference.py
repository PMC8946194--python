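"""Published group-level summaries from the motivating dual-task study.

These numbers are *inputs*, not outputs: the study (16 adults, verbal
estimation of 13-132 s intervals under four cognitive tasks while sitting or
walking) published per-cell group means of the verbal estimates and the
parameters of linear fits to the 2-s-binned estimation bias and RMSE.  They
serve three purposes here:

* default generative parameters for :mod:`prostime.synthetic_data` (offset =
  bias intercept, gain = 1 + bias slope),
* cross-check fixtures for the analysis chain (refitting the per-interval
  mean biases must land near the published slopes), and
* the worked percent-effect arithmetic of the motor-vs-cognitive comparison.
"""

from __future__ import annotations

import pandas as pd

TASKS = ("look", "read", "solve_simple", "solve_hard")
CONDITIONS = ("sitting", "walking")
NOMINAL_INTERVALS = (15, 30, 60, 90, 120)

# Group mean verbal estimate (s) and its SE across participants, per
# (condition, task, nominal interval).
_GROUP_MEANS = {
    ("sitting", "look"): [(21.8, 1.5), (35.6, 1.7), (66.3, 2.8), (97.3, 3.2), (122.9, 3.4)],
    ("sitting", "read"): [(18.1, 1.2), (31.8, 1.7), (58.5, 2.4), (87.3, 1.7), (110.3, 3.4)],
    ("sitting", "solve_simple"): [(14.4, 0.7), (27.1, 1.1), (51.5, 1.7), (73.6, 2.8), (94.7, 4.3)],
    ("sitting", "solve_hard"): [(12.7, 0.7), (23.1, 1.1), (45.2, 2.2), (65.9, 2.9), (86.7, 3.9)],
    ("walking", "look"): [(24.4, 1.8), (38.7, 2.4), (71.2, 3.8), (100.6, 4.5), (124.0, 4.7)],
    ("walking", "read"): [(19.4, 1.5), (31.8, 1.9), (58.2, 3.9), (87.8, 4.5), (110.8, 5.4)],
    ("walking", "solve_simple"): [(13.6, 1.1), (23.7, 1.3), (45.1, 2.5), (66.2, 4.1), (83.7, 4.7)],
    ("walking", "solve_hard"): [(10.9, 0.8), (20.8, 1.4), (38.6, 2.6), (55.9, 3.1), (71.9, 4.6)],
}

# Published linear fits of estimation bias (e - d, seconds) against duration,
# from 2-s binned data: intercept +/- SE (s), slope +/- SE (s/s), chi^2 with
# 35 degrees of freedom.
BIAS_FIT_REFERENCE = {
    ("sitting", "look"): {"intercept": 6.4, "intercept_se": 0.9, "slope": 0.005, "slope_se": 0.2, "chi2": 45.9, "df": 35},
    ("sitting", "read"): {"intercept": 4.8, "intercept_se": 0.8, "slope": -0.09, "slope_se": 0.2, "chi2": 50.1, "df": 35},
    ("sitting", "solve_simple"): {"intercept": 2.8, "intercept_se": 0.6, "slope": -0.2, "slope_se": 0.2, "chi2": 57.8, "df": 35},
    ("sitting", "solve_hard"): {"intercept": 1.2, "intercept_se": 0.4, "slope": -0.3, "slope_se": 0.01, "chi2": 36.1, "df": 35},
    ("walking", "look"): {"intercept": 8.9, "intercept_se": 0.8, "slope": 0.01, "slope_se": 0.2, "chi2": 35.6, "df": 35},
    ("walking", "read"): {"intercept": 5.7, "intercept_se": 0.8, "slope": -0.1, "slope_se": 0.2, "chi2": 41.6, "df": 35},
    ("walking", "solve_simple"): {"intercept": 3.3, "intercept_se": 0.6, "slope": -0.3, "slope_se": 0.2, "chi2": 40.0, "df": 35},
    ("walking", "solve_hard"): {"intercept": 1.8, "intercept_se": 0.4, "slope": -0.4, "slope_se": 0.01, "chi2": 36.7, "df": 35},
}

# Published linear fits of per-bin RMSE (s) against duration (slope is close
# to the coefficient of variation; intercept in seconds).
RMSE_FIT_REFERENCE = {
    ("sitting", "look"): {"slope": 0.14, "slope_se": 0.02, "intercept": 4.6, "intercept_se": 0.2},
    ("sitting", "read"): {"slope": 0.16, "slope_se": 0.01, "intercept": 4.1, "intercept_se": 0.4},
    ("sitting", "solve_simple"): {"slope": 0.22, "slope_se": 0.02, "intercept": 1.7, "intercept_se": 0.1},
    ("sitting", "solve_hard"): {"slope": 0.21, "slope_se": 0.01, "intercept": 0.8, "intercept_se": 0.1},
    ("walking", "look"): {"slope": 0.22, "slope_se": 0.1, "intercept": 4.9, "intercept_se": 0.1},
    ("walking", "read"): {"slope": 0.23, "slope_se": 0.01, "intercept": 3.2, "intercept_se": 0.2},
    ("walking", "solve_simple"): {"slope": 0.21, "slope_se": 0.01, "intercept": 1.2, "intercept_se": 0.1},
    ("walking", "solve_hard"): {"slope": 0.23, "slope_se": 0.02, "intercept": 0.9, "intercept_se": 0.2},
}

# Math-task performance: mean accuracy (proportion correct) and mean response
# time (s) per (condition, task).
PERFORMANCE_REFERENCE = {
    ("sitting", "solve_simple"): {"accuracy": 0.996, "rt_mean_s": 1.45},
    ("sitting", "solve_hard"): {"accuracy": 0.947, "rt_mean_s": 3.02},
    ("walking", "solve_simple"): {"accuracy": 0.996, "rt_mean_s": 1.62},
    ("walking", "solve_hard"): {"accuracy": 0.913, "rt_mean_s": 3.16},
}

# Per-block trends of the control covariates (slope per block, t on 8 df).
COVARIATE_TREND_REFERENCE = {
    ("sitting", "physical_fatigue"): {"slope": 0.01, "t": 2.1},
    ("walking", "physical_fatigue"): {"slope": 0.15, "t": 6.9},
    ("sitting", "mental_tiredness"): {"slope": 0.13, "t": 6.9},
    ("walking", "mental_tiredness"): {"slope": 0.16, "t": 8.1},
    ("sitting", "body_temp_c"): {"slope": 0.002, "t": 0.9},
    ("walking", "body_temp_c"): {"slope": 0.0003, "t": 0.06},
}


def group_mean_estimates() -> pd.DataFrame:
    """Published per-cell group means as a tidy frame.

    Columns: condition, task, nominal_s, mean_estimate, se, mean_bias
    (mean_bias = mean_estimate - nominal interval; the jitter windows are
    symmetric so the mean actual duration equals the nominal one).
    """
    rows = []
    for (condition, task), cells in _GROUP_MEANS.items():
        for nominal, (mean, se) in zip(NOMINAL_INTERVALS, cells):
            rows.append(
                {
                    "condition": condition,
                    "task": task,
                    "nominal_s": nominal,
                    "mean_estimate": mean,
                    "se": se,
                    "mean_bias": mean - nominal,
                }
            )
    return pd.DataFrame(rows)
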