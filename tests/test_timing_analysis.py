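"""Bias computation, 2-s binning, weighted fits, CV estimates, accuracy
tests, percent effects and performance summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from prostime import reference
from prostime.synthetic_data import (
    CONDITIONS,
    TASKS,
    DesignSpec,
    GenerativeParams,
    generate_design,
    linear_clock_model,
    attach_performance,
)
from prostime.timing_analysis import (
    accuracy_tests,
    cell_summary,
    compute_bias,
    effect_summaries,
    effect_summaries_from_cell_means,
    fit_bias_line,
    fit_line,
    fit_rmse_line,
    make_bins,
    performance_summaries,
)


def lstsq_oracle(x, y, se, through_origin=False):
    """Independent weighted-fit oracle: least squares on the sqrt-weight
    transformed design matrix."""
    x, y, se = map(np.asarray, (x, y, se))
    if through_origin:
        a = (x / se)[:, None]
    else:
        a = np.column_stack([1 / se, x / se])
    coef, *_ = np.linalg.lstsq(a, y / se, rcond=None)
    cov = np.linalg.inv(a.T @ a)
    return coef, np.sqrt(np.diag(cov))


def identity_params(cv=0.0):
    return {
        (t, c): GenerativeParams(0, 1, cv=cv, outlier_rate=0)
        for t in TASKS
        for c in CONDITIONS
    }


class TestComputeBias:
    def test_perfect_estimates_have_zero_bias(self, small_design):
        trials = linear_clock_model(small_design, identity_params(), seed=0)
        bias = compute_bias(trials, apply_filter=False)
        assert np.allclose(bias["bias"], 0)
        assert bias["kept"].all()

    def test_filter_flags_injected_outlier_per_cell(self, small_design):
        trials = linear_clock_model(small_design, identity_params(cv=0.05), seed=1)
        idx = trials[(trials.task == "look") & (trials.condition == "sitting")
                     & (trials.nominal_s == 60)].index[0]
        trials.loc[idx, "estimate_s"] = 600.0
        bias = compute_bias(trials)
        assert not bias.loc[idx, "kept"]
        # only genuine tail trials are touched elsewhere (3 SD of a cv=0.05 law)
        assert (~bias["kept"]).mean() < 0.01


class TestMakeBins:
    def test_default_scheme_yields_37_bins_per_cell(self, full_bias):
        binned = make_bins(full_bias)
        counts = binned.groupby(["condition", "task"]).size()
        assert (counts == 37).all()
        per_window = binned.groupby(["condition", "task", "nominal_s"]).size().unstack()
        assert list(per_window.iloc[0]) == [3, 4, 7, 10, 13]

    def test_bin_counts_sum_to_filtered_trials(self, full_bias):
        binned = make_bins(full_bias)
        assert binned["n"].sum() == int(full_bias["kept"].sum())

    def test_single_duration_gives_one_bin(self):
        df = pd.DataFrame(
            {
                "condition": "sitting",
                "task": "look",
                "nominal_s": 15,
                "actual_s": 15,
                "estimate_s": [20.0, 21.0, 22.0, 23.0],
                "bias": [5.0, 6.0, 7.0, 8.0],
                "kept": True,
            }
        )
        binned = make_bins(df)
        assert len(binned) == 1
        assert binned.loc[0, "center_s"] == 15.5  # bin [15, 16] of the 13-17 window

    def test_two_parameter_fit_has_35_df(self, full_bias):
        binned = make_bins(full_bias)
        g = binned[(binned.condition == "sitting") & (binned.task == "look")]
        assert fit_bias_line(g).df == 35


class TestFitLine:
    def test_noiseless_line_recovered_exactly(self):
        x = np.array([10.0, 20, 30, 40])
        y = 2.5 * x - 3
        fit = fit_line(x, y, se=np.ones(4))
        assert fit.slope == pytest.approx(2.5)
        assert fit.intercept == pytest.approx(-3)
        assert fit.chi2 == pytest.approx(0, abs=1e-18)

    def test_weighted_fit_matches_lstsq_oracle(self):
        x = np.array([13.0, 60.0, 130.0])
        y = np.array([5.0, 1.0, -20.0])
        se = np.array([0.5, 1.0, 2.0])
        fit = fit_line(x, y, se=se)
        coef, ses = lstsq_oracle(x, y, se)
        assert fit.intercept == pytest.approx(coef[0])
        assert fit.slope == pytest.approx(coef[1])
        assert fit.intercept_se == pytest.approx(ses[0])
        assert fit.slope_se == pytest.approx(ses[1])

    def test_through_origin_weighted_slope_closed_form(self):
        x = np.array([20.0, 60.0, 120.0])
        y = np.array([4.2, 12.5, 23.0])
        se = np.array([0.4, 0.7, 1.5])
        fit = fit_line(x, y, se=se, through_origin=True)
        w = 1 / se**2
        assert fit.slope == pytest.approx((w * x * y).sum() / (w * x * x).sum())
        coef, ses = lstsq_oracle(x, y, se, through_origin=True)
        assert fit.slope == pytest.approx(coef[0])
        assert fit.slope_se == pytest.approx(ses[0])

    def test_zero_se_bins_get_floored_weight(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([1.0, 2, 3, 4])
        fit = fit_line(x, y, se=np.array([0.0, 0.1, 0.1, 0.1]))
        assert np.isfinite(fit.slope) and fit.slope == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_line([1, 2], [1, 2], se=[1, 1])


class TestReferenceTableFits:
    """Refitting the published per-interval mean biases (unweighted OLS on the
    five nominal intervals) must land close to the published binned-fit
    slopes."""

    @pytest.mark.parametrize(
        "condition, task",
        [
            ("sitting", "solve_simple"),
            ("sitting", "solve_hard"),
            ("walking", "solve_simple"),
            ("walking", "solve_hard"),
        ],
    )
    def test_solve_task_slopes(self, condition, task):
        table = reference.group_mean_estimates()
        g = table[(table.condition == condition) & (table.task == task)]
        fit = fit_line(g["nominal_s"], g["mean_bias"])
        published = reference.BIAS_FIT_REFERENCE[(condition, task)]["slope"]
        assert fit.slope == pytest.approx(published, abs=0.05)

    def test_solve_hard_sitting_value(self):
        table = reference.group_mean_estimates()
        g = table[(table.condition == "sitting") & (table.task == "solve_hard")]
        fit = fit_line(g["nominal_s"], g["mean_bias"])
        assert fit.slope == pytest.approx(-0.2935, abs=1e-3)

    def test_table_mean_biases(self):
        table = reference.group_mean_estimates().set_index(["condition", "task", "nominal_s"])
        assert table.loc[("sitting", "solve_hard", 120), "mean_bias"] == pytest.approx(-33.3)
        assert table.loc[("sitting", "look", 15), "mean_bias"] == pytest.approx(6.8)


class TestRmseFits:
    def test_exact_proportional_rmse_gives_cv(self):
        binned = pd.DataFrame(
            {
                "center_s": [20.0, 60.0, 120.0],
                "mean_estimate": [25.0, 65.0, 125.0],
                "rmse": [5.0, 13.0, 25.0],
                "n": [50, 50, 50],
            }
        )
        cv = fit_rmse_line(binned, mode="vs_estimate_origin")
        assert cv.cv == pytest.approx(0.2)
        assert cv.chi2 == pytest.approx(0, abs=1e-18)

    def test_vs_duration_recovers_generator_cv(self, full_bias):
        binned = make_bins(full_bias)
        g = binned[(binned.condition == "sitting") & (binned.task == "look")]
        fit = fit_rmse_line(g, mode="vs_duration")
        # RMSE ~ cv * (offset + gain*d): slope ~ cv * gain = 0.2 * 1.005
        assert abs(fit.slope - 0.201) < 2.5 * fit.slope_se

    def test_cv_estimate_close_to_generator_cv(self, full_bias):
        binned = make_bins(full_bias)
        g = binned[(binned.condition == "sitting") & (binned.task == "read")]
        cv = fit_rmse_line(g, mode="vs_estimate_origin")
        assert cv.cv == pytest.approx(0.2, abs=0.03)

    def test_unknown_mode_rejected(self, full_bias):
        with pytest.raises(ValueError):
            fit_rmse_line(make_bins(full_bias), mode="nope")


class TestAccuracyTests:
    def test_forced_positive_bias_is_detected_at_short_intervals(self):
        design = generate_design(DesignSpec(n_participants=10, rng_seed=31))
        params = {
            (t, c): GenerativeParams(6, 1, cv=0.2, outlier_rate=0)
            for t in TASKS
            for c in CONDITIONS
        }
        trials = linear_clock_model(design, params, seed=32)
        table = accuracy_tests(compute_bias(trials))
        short = table[table.nominal_s == 15]
        assert short["significant"].all()
        assert (short["mean_bias"] > 0).all()

    def test_determinism_duplicate_cells_agree(self, full_bias):
        a = accuracy_tests(full_bias)
        b = accuracy_tests(full_bias.copy())
        pd.testing.assert_frame_equal(a, b)

    def test_bonferroni_family_is_within_condition(self, full_bias):
        table = accuracy_tests(full_bias)
        for _, g in table.groupby("condition"):
            m = len(g)
            expected = np.minimum(1.0, g["p"] * m)
            assert np.allclose(g["p_adj"], expected)


class TestEffects:
    def test_published_table_motor_effect(self):
        cells = reference.group_mean_estimates()
        report = effect_summaries_from_cell_means(cells)
        assert report["motor"]["per_interval"][15] == pytest.approx(17.33, abs=0.01)
        assert report["motor"]["max"] == pytest.approx(17.33, abs=0.01)
        assert report["motor"]["mean"] == pytest.approx(8.08, abs=0.05)
        assert report["cognitive_combined"]["mean"] == pytest.approx(35.5, abs=0.5)
        assert report["cognitive_combined"]["max"] == pytest.approx(60.7, abs=0.5)

    def test_identical_conditions_give_zero_motor_effect(self):
        cells = reference.group_mean_estimates()
        sit = cells[cells.condition == "sitting"].copy()
        walk = sit.copy()
        walk["condition"] = "walking"
        report = effect_summaries_from_cell_means(pd.concat([sit, walk]))
        assert all(v == 0 for v in report["motor"]["per_interval"].values())

    def test_missing_cells_reported_as_warnings(self):
        cells = reference.group_mean_estimates()
        cells = cells[~((cells.task == "look") & (cells.nominal_s == 15))]
        report = effect_summaries_from_cell_means(cells)
        assert report["warnings"]
        assert 15 not in report["motor"]["per_interval"]

    def test_end_to_end_effects_from_simulation(self, full_bias):
        report = effect_summaries(full_bias)
        # caption parameters imply positive motor and cognitive effects
        assert report["motor"]["mean"] > 0
        assert report["cognitive_combined"]["mean"] > 20


class TestPerformance:
    def test_all_correct_gives_100_pct(self, small_design):
        trials = linear_clock_model(small_design, seed=0)
        trials["correct"] = np.where(trials.task.str.startswith("solve"), 1.0, np.nan)
        trials["rt_s"] = np.where(trials.task.str.startswith("solve"), 2.0, np.nan)
        report = performance_summaries(trials)
        for cell in report["cells"].values():
            assert cell["accuracy_pct"] == 100

    def test_configured_accuracy_and_rt_recovered(self):
        design = generate_design(DesignSpec(rng_seed=41))
        trials = attach_performance(linear_clock_model(design, seed=42), seed=43)
        report = performance_summaries(trials)
        hard_walk = report["cells"]["solve_hard:walking"]
        assert hard_walk["accuracy_pct"] == pytest.approx(91.3, abs=1.5)
        hard_sit = report["cells"]["solve_hard:sitting"]
        assert hard_sit["rt_mean_s"] == pytest.approx(3.02, abs=0.1)
        paired = report["rt_paired_walking_minus_sitting"]
        assert paired["solve_simple"]["n_participants"] == 16

    def test_missing_columns_rejected(self, small_design):
        with pytest.raises(ValueError):
            performance_summaries(linear_clock_model(small_design, seed=0))


def test_cell_summary_counts_and_means(full_bias):
    cells = cell_summary(full_bias)
    assert len(cells) == 40
    assert (cells["n_trials"] == cells["n_kept"] + cells["n_removed"]).all()
    look15 = cells[(cells.condition == "sitting") & (cells.task == "look")
                   & (cells.nominal_s == 15)].iloc[0]
    # caption parameters: expected mean estimate ~ 6.4 + 1.005 * 15
    assert look15["mean_estimate"] == pytest.approx(21.5, abs=1.5)
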