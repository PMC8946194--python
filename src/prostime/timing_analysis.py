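"""Estimation-bias analysis: filtering, 2-s binning, weighted line fits,
scalar-timing (coefficient-of-variation) fits, accuracy tests, and percent
effect summaries.

Conventions
-----------
* Bias is estimate minus true duration (positive = overestimation).
* The outlier filter acts on the raw per-cell estimate distributions
  (cell = task x condition x nominal interval), pooled across participants.
* Bins are 2-s partitions of each nominal interval's integer jitter window,
  anchored at the window minimum; the default design yields 3+4+7+10+13 = 37
  bins per (task, condition), hence 35 degrees of freedom for two-parameter
  fits.
* Per-bin dispersion (RMSE) is computed about the bin mean by default —
  i.e. it measures the *variability* of the estimates, not their accuracy —
  with an about-truth variant behind a flag.
* Bin-level fits are weighted by 1/SE^2 with parameter covariance taken from
  the weighted normal equations (SEs treated as known), so the weighted
  residual sum chi^2 = sum((y - yhat)/SE)^2 is a goodness-of-fit statistic
  with n_bins - n_params degrees of freedom.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .robust_stats import bonferroni, filter_outliers, wilcoxon_signed_rank, WilcoxonResult
from .synthetic_data import SOLVE_TASKS, jitter_window

logger = logging.getLogger(__name__)

__all__ = [
    "LinearFit",
    "CVEstimate",
    "compute_bias",
    "make_bins",
    "fit_line",
    "fit_bias_line",
    "fit_rmse_line",
    "accuracy_tests",
    "effect_summaries",
    "effect_summaries_from_cell_means",
    "performance_summaries",
    "cell_summary",
]

CELL_KEYS = ["condition", "task", "nominal_s"]


@dataclass
class LinearFit:
    """Straight-line fit y = a + b x (or y = b x through the origin)."""

    slope: float
    slope_se: float
    intercept: float | None
    intercept_se: float | None
    chi2: float
    df: int
    n_points: int
    weighted: bool


@dataclass
class CVEstimate:
    """Coefficient of variation: through-origin slope of per-bin RMSE against
    per-bin mean estimated time."""

    cv: float
    se: float
    chi2: float
    df: int
    n_points: int


def compute_bias(
    trials: pd.DataFrame, apply_filter: bool = True, k: float = 3.0
) -> pd.DataFrame:
    """Per-trial estimation bias with an outlier provenance mask.

    Adds ``bias`` (estimate_s - actual_s) and boolean ``kept``.  When
    ``apply_filter`` is on, the pseudomedian +/- k*SD filter runs on the
    estimate distribution of every (condition, task, nominal interval) cell,
    pooled across participants.
    """
    required = {"condition", "task", "nominal_s", "actual_s", "estimate_s"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trials frame lacks columns: {sorted(missing)}")
    out = trials.copy()
    out["bias"] = out["estimate_s"] - out["actual_s"]
    kept = np.ones(len(out), dtype=bool)
    if apply_filter:
        positions = pd.Series(np.arange(len(out)), index=out.index)
        for cell, idx in out.groupby(CELL_KEYS, sort=False).groups.items():
            res = filter_outliers(out.loc[idx, "estimate_s"].to_numpy(), k=k)
            kept[positions[idx].to_numpy()] = res.kept_mask
            if res.kept.size == 0:
                logger.warning("cell %s empty after filtering", cell)
    out["kept"] = kept
    return out


def make_bins(
    bias_table: pd.DataFrame,
    width: int = 2,
    jitter_fraction: float = 0.10,
    rmse_about: str = "bin_mean",
    min_bin_n: int = 2,
    se_method: str = "pooled",
) -> pd.DataFrame:
    """Average filtered biases over ``width``-second duration bins.

    Bins are anchored at each nominal interval's jitter-window minimum; the
    final bin of an odd-width window covers a single duration.  Returns one
    row per (condition, task, bin) with the bin centre, mean bias, SE,
    RMSE, mean estimate and trial count.  Bins with fewer than ``min_bin_n``
    kept trials are dropped (logged).

    ``se_method`` controls the SE of the per-bin mean bias used as fit
    weights.  "pooled" (default) divides a dispersion pooled over the bins of
    the same nominal-interval cell by sqrt(n_bin): within a +/-10% jitter
    window the scalar property keeps the trial-level SD nearly constant, and
    pooling removes the small-sample bias of a per-bin SD (which otherwise
    inflates chi^2 by roughly (n-1)/(n-3) and makes parameter SEs
    anti-conservative).  "per_bin" uses each bin's own SD/sqrt(n).
    """
    if width not in (2, 3):
        raise ValueError("bin width must be 2 or 3 seconds")
    if rmse_about not in ("bin_mean", "truth"):
        raise ValueError("rmse_about must be 'bin_mean' or 'truth'")
    if se_method not in ("pooled", "per_bin"):
        raise ValueError("se_method must be 'pooled' or 'per_bin'")
    kept = bias_table[bias_table["kept"]] if "kept" in bias_table.columns else bias_table
    rows = []
    for (condition, task), group in kept.groupby(["condition", "task"], sort=False):
        for nominal, cell in group.groupby("nominal_s", sort=True):
            lo, hi = jitter_window(int(nominal), jitter_fraction)
            d = cell["actual_s"].to_numpy()
            bias = cell["bias"].to_numpy(dtype=float)
            est = cell["estimate_s"].to_numpy(dtype=float)
            outside = int(((d < lo) | (d > hi)).sum())
            if outside:
                logger.warning(
                    "%d trials outside the %s s jitter window in cell (%s, %s)",
                    outside, nominal, condition, task,
                )
            cell_rows = []
            for b_lo in range(lo, hi + 1, width):
                b_hi = min(b_lo + width - 1, hi)
                sel = (d >= b_lo) & (d <= b_hi)
                n = int(sel.sum())
                if n < min_bin_n:
                    logger.info(
                        "dropping bin [%d, %d] of cell (%s, %s, %s): n = %d",
                        b_lo, b_hi, condition, task, nominal, n,
                    )
                    continue
                b = bias[sel]
                mean_bias = float(b.mean())
                sd = float(b.std(ddof=1))
                if rmse_about == "bin_mean":
                    rmse = float(np.sqrt(np.mean((b - mean_bias) ** 2)))
                else:
                    rmse = float(np.sqrt(np.mean(b**2)))
                cell_rows.append(
                    {
                        "condition": condition,
                        "task": task,
                        "nominal_s": nominal,
                        "bin_lo": b_lo,
                        "bin_hi": b_hi,
                        "center_s": (b_lo + b_hi) / 2.0,
                        "n": n,
                        "sd": sd,
                        "mean_bias": mean_bias,
                        "se": sd / math.sqrt(n),
                        "rmse": rmse,
                        "mean_estimate": float(est[sel].mean()),
                    }
                )
            if se_method == "pooled" and cell_rows:
                num = sum((r["n"] - 1) * r["sd"] ** 2 for r in cell_rows)
                den = sum(r["n"] - 1 for r in cell_rows)
                if den > 0 and num > 0:
                    pooled_sd = math.sqrt(num / den)
                    for r in cell_rows:
                        r["se"] = pooled_sd / math.sqrt(r["n"])
                        # RMSE uncertainty from the pooled scale too, so the
                        # fit weights are not correlated with the response
                        r["rmse_se"] = pooled_sd / math.sqrt(2 * max(r["n"] - 1, 1))
            rows.extend(cell_rows)
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.drop(columns=["sd"])
    return frame


def _positive_floor(se: np.ndarray) -> np.ndarray:
    """Replace non-positive / non-finite SEs by the smallest positive SE.

    If no positive SE exists at all (noiseless data), unit SEs are used so
    the fit degrades to equal weights.
    """
    se = np.asarray(se, dtype=float).copy()
    bad = ~np.isfinite(se) | (se <= 0)
    if bad.all():
        logger.warning("all bin SEs are zero; falling back to equal weights")
        return np.ones_like(se)
    if bad.any():
        se[bad] = se[~bad].min()
    return se


def fit_line(
    x: Sequence[float],
    y: Sequence[float],
    se: Sequence[float] | None = None,
    through_origin: bool = False,
) -> LinearFit:
    """Least-squares line fit, weighted by 1/SE^2 when SEs are given.

    Weighted fits treat the SEs as known: parameter covariance comes from the
    weighted normal equations and chi2 = sum((y - yhat)/SE)^2 is reported as
    a goodness-of-fit statistic.  Unweighted fits report classical OLS
    standard errors (residual-variance based) and chi2 = NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    n_params = 1 if through_origin else 2
    if n < n_params + 1:
        raise ValueError(f"need at least {n_params + 1} points, got {n}")

    if se is not None:
        se = _positive_floor(se)
        w = 1.0 / se**2
        if through_origin:
            sxx = float((w * x * x).sum())
            slope = float((w * x * y).sum()) / sxx
            slope_se = math.sqrt(1.0 / sxx)
            resid = (y - slope * x) / se
            return LinearFit(slope, slope_se, None, None, float((resid**2).sum()),
                             n - 1, n, True)
        sw = float(w.sum())
        swx = float((w * x).sum())
        swxx = float((w * x * x).sum())
        a_mat = np.array([[sw, swx], [swx, swxx]])
        b_vec = np.array([float((w * y).sum()), float((w * x * y).sum())])
        cov = np.linalg.inv(a_mat)
        intercept, slope = cov @ b_vec
        resid = (y - intercept - slope * x) / se
        return LinearFit(
            slope=float(slope),
            slope_se=math.sqrt(cov[1, 1]),
            intercept=float(intercept),
            intercept_se=math.sqrt(cov[0, 0]),
            chi2=float((resid**2).sum()),
            df=n - 2,
            n_points=n,
            weighted=True,
        )

    if through_origin:
        sxx = float((x * x).sum())
        slope = float((x * y).sum()) / sxx
        rss = float(((y - slope * x) ** 2).sum())
        s2 = rss / (n - 1)
        return LinearFit(slope, math.sqrt(s2 / sxx), None, None, float("nan"),
                         n - 1, n, False)
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    slope = float(((x - xbar) * (y - ybar)).sum()) / sxx
    intercept = ybar - slope * xbar
    rss = float(((y - intercept - slope * x) ** 2).sum())
    s2 = rss / (n - 2) if n > 2 else float("nan")
    slope_se = math.sqrt(s2 / sxx)
    intercept_se = math.sqrt(s2 * (1.0 / n + xbar**2 / sxx))
    return LinearFit(slope, slope_se, intercept, intercept_se, float("nan"),
                     n - 2, n, False)


def fit_bias_line(binned: pd.DataFrame, n_params: int = 2) -> LinearFit:
    """Weighted fit of per-bin mean bias against bin-centre duration."""
    if n_params not in (1, 2):
        raise ValueError("n_params must be 1 or 2")
    if len(binned) < n_params + 1:
        raise ValueError("not enough usable bins for the requested fit")
    return fit_line(
        binned["center_s"], binned["mean_bias"], se=binned["se"],
        through_origin=(n_params == 1),
    )


def _rmse_se(binned: pd.DataFrame) -> np.ndarray:
    # Large-sample SE of an RMSE estimated from n Gaussian residuals.  A
    # pooled version (rmse_se column) is preferred when make_bins produced
    # one, so the weights stay independent of each bin's own sampling noise.
    if "rmse_se" in binned.columns and binned["rmse_se"].notna().all():
        return _positive_floor(binned["rmse_se"].to_numpy(dtype=float))
    n = binned["n"].to_numpy(dtype=float)
    rmse = binned["rmse"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = rmse / np.sqrt(2.0 * np.maximum(n - 1, 1))
    return _positive_floor(se)


def fit_rmse_line(
    binned: pd.DataFrame, mode: str = "vs_duration"
) -> LinearFit | CVEstimate:
    """Fit per-bin RMSE against duration or against mean estimated time.

    mode="vs_duration": two-parameter weighted fit of RMSE on bin centre.
    mode="vs_estimate_origin": one-parameter through-origin weighted fit of
    RMSE on the per-bin mean estimate; the slope is the coefficient of
    variation (scalar-timing summary), returned as :class:`CVEstimate`.
    """
    if len(binned) < 2:
        raise ValueError("need at least 2 usable bins")
    se = _rmse_se(binned)
    if mode == "vs_duration":
        return fit_line(binned["center_s"], binned["rmse"], se=se)
    if mode == "vs_estimate_origin":
        fit = fit_line(binned["mean_estimate"], binned["rmse"], se=se, through_origin=True)
        return CVEstimate(cv=fit.slope, se=fit.slope_se, chi2=fit.chi2,
                          df=fit.df, n_points=fit.n_points)
    raise ValueError(f"unknown mode: {mode!r}")


def accuracy_tests(
    bias_table: pd.DataFrame, alpha: float = 0.05, min_n: int = 5
) -> pd.DataFrame:
    """Per-cell one-sample Wilcoxon tests of the bias against zero.

    Biases are first averaged per participant within each (condition, task,
    nominal interval) cell, matching a by-participant test; the Bonferroni
    family is the set of cells within each motor condition.
    """
    kept = bias_table[bias_table["kept"]] if "kept" in bias_table.columns else bias_table
    per_participant = (
        kept.groupby(CELL_KEYS + ["participant_id"], sort=True)["bias"].mean().reset_index()
    )
    rows = []
    for (condition, task, nominal), g in per_participant.groupby(CELL_KEYS, sort=True):
        values = g["bias"].to_numpy()
        res: WilcoxonResult = wilcoxon_signed_rank(values)
        rows.append(
            {
                "condition": condition,
                "task": task,
                "nominal_s": nominal,
                "n_participants": values.size,
                "V": res.statistic,
                "n_effective": res.n_effective,
                "p": res.p_value,
                "method": res.method,
                "small_cell": values.size < min_n,
                "mean_bias": float(values.mean()),
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = np.nan
    for condition, idx in table.groupby("condition").groups.items():
        table.loc[idx, "p_adj"] = bonferroni(table.loc[idx, "p"].to_numpy())
    table["significant"] = table["p_adj"] < alpha
    return table


def _cell_mean_estimates(bias_table: pd.DataFrame) -> pd.DataFrame:
    kept = bias_table[bias_table["kept"]] if "kept" in bias_table.columns else bias_table
    cells = kept.groupby(CELL_KEYS, sort=True)["estimate_s"].mean().reset_index()
    return cells.rename(columns={"estimate_s": "mean_estimate"})


def effect_summaries_from_cell_means(cell_means: pd.DataFrame) -> dict:
    """Percent motor and cognitive effects from per-cell mean estimates.

    Motor effect per interval T: (mean estimate walking - sitting) / T in the
    look task.  Cognitive effect per interval: (mean estimate look - solve) /
    T in the sitting condition, reported per solve task and combined.  All
    values are percentages of the nominal interval.
    """
    table = cell_means.set_index(["condition", "task", "nominal_s"])["mean_estimate"]

    def cell(condition: str, task: str, nominal: int) -> float | None:
        try:
            return float(table.loc[(condition, task, nominal)])
        except KeyError:
            return None

    intervals = sorted(cell_means["nominal_s"].unique())
    warnings: list[str] = []

    motor: dict[int, float] = {}
    for t in intervals:
        walk, sit = cell("walking", "look", t), cell("sitting", "look", t)
        if walk is None or sit is None:
            warnings.append(f"missing look cell at {t} s; motor effect skipped")
            continue
        motor[int(t)] = 100.0 * (walk - sit) / t

    cognitive: dict[str, dict[int, float]] = {}
    for solve in SOLVE_TASKS:
        eff: dict[int, float] = {}
        for t in intervals:
            look, sol = cell("sitting", "look", t), cell("sitting", solve, t)
            if look is None or sol is None:
                warnings.append(f"missing {solve} cell at {t} s; cognitive effect skipped")
                continue
            eff[int(t)] = 100.0 * (look - sol) / t
        cognitive[solve] = eff

    def summarise(d: Mapping[int, float]) -> dict:
        vals = list(d.values())
        return {
            "per_interval": dict(d),
            "mean": float(np.mean(vals)) if vals else float("nan"),
            "max": float(np.max(vals)) if vals else float("nan"),
        }

    all_cog = [v for eff in cognitive.values() for v in eff.values()]
    return {
        "motor": summarise(motor),
        "cognitive": {k: summarise(v) for k, v in cognitive.items()},
        "cognitive_combined": {
            "mean": float(np.mean(all_cog)) if all_cog else float("nan"),
            "max": float(np.max(all_cog)) if all_cog else float("nan"),
        },
        "warnings": warnings,
    }


def effect_summaries(bias_table: pd.DataFrame) -> dict:
    """Percent motor/cognitive effect report from a (filtered) bias table."""
    return effect_summaries_from_cell_means(_cell_mean_estimates(bias_table))


def performance_summaries(trials: pd.DataFrame) -> dict:
    """Descriptive accuracy / response-time summaries for the math tasks.

    Accuracy and RT are averaged per participant first; the reported mean and
    SE are across participants.  Paired walking-minus-sitting RT differences
    are reported per task for participants measured in both conditions.
    """
    if "correct" not in trials.columns or "rt_s" not in trials.columns:
        raise ValueError("trials frame lacks 'correct'/'rt_s' columns")
    solve = trials[trials["task"].isin(SOLVE_TASKS)].dropna(subset=["correct", "rt_s"])
    per_participant = (
        solve.groupby(["condition", "task", "participant_id"])
        .agg(accuracy=("correct", "mean"), rt=("rt_s", "mean"))
        .reset_index()
    )
    cells = {}
    for (condition, task), g in per_participant.groupby(["condition", "task"]):
        n = len(g)
        cells[f"{task}:{condition}"] = {
            "accuracy_pct": float(g["accuracy"].mean() * 100),
            "accuracy_pct_se": float(g["accuracy"].std(ddof=1) / math.sqrt(n) * 100) if n > 1 else float("nan"),
            "rt_mean_s": float(g["rt"].mean()),
            "rt_se_s": float(g["rt"].std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan"),
            "n_participants": n,
        }
    paired = {}
    wide = per_participant.pivot_table(
        index=["task", "participant_id"], columns="condition", values="rt"
    )
    if {"sitting", "walking"} <= set(wide.columns):
        both = wide.dropna(subset=["sitting", "walking"])
        for task, g in both.groupby(level="task"):
            diff = (g["walking"] - g["sitting"]).to_numpy()
            paired[task] = {
                "rt_diff_mean_s": float(diff.mean()),
                "rt_diff_se_s": float(diff.std(ddof=1) / math.sqrt(diff.size)) if diff.size > 1 else float("nan"),
                "n_participants": int(diff.size),
            }
    return {"cells": cells, "rt_paired_walking_minus_sitting": paired}


def cell_summary(bias_table: pd.DataFrame) -> pd.DataFrame:
    """Group-mean estimate per cell with SE across participants, plus kept /
    removed trial counts (the published-table analogue)."""
    per_participant = (
        bias_table[bias_table["kept"]]
        .groupby(CELL_KEYS + ["participant_id"])[["estimate_s", "bias"]]
        .mean()
        .reset_index()
    )
    rows = []
    for (condition, task, nominal), g in per_participant.groupby(CELL_KEYS, sort=True):
        vals = g["estimate_s"].to_numpy()
        biases = g["bias"].to_numpy()
        cell_mask = (
            (bias_table["condition"] == condition)
            & (bias_table["task"] == task)
            & (bias_table["nominal_s"] == nominal)
        )
        n_total = int(cell_mask.sum())
        n_kept = int((cell_mask & bias_table["kept"]).sum())
        rows.append(
            {
                "condition": condition,
                "task": task,
                "nominal_s": nominal,
                "mean_estimate": float(vals.mean()),
                "se": float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else float("nan"),
                "mean_bias": float(biases.mean()),
                "n_trials": n_total,
                "n_kept": n_kept,
                "n_removed": n_total - n_kept,
            }
        )
    return pd.DataFrame(rows)
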