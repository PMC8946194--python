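"""Synthetic dual-task time-estimation experiments.

Emulates a prospective verbal time-estimation study: participants estimate
intervals jittered around {15, 30, 60, 90, 120} s while performing one of
four cognitive tasks (look, read, solve_simple, solve_hard) in two motor
conditions (sitting, walking on a treadmill).  Trials come in blocks that
contain every nominal interval exactly twice, tasks are randomised across
blocks subject to a fixed per-cell quota, and actual durations are integer
seconds drawn uniformly from a +/-10% window around the nominal value.

Two interchangeable generative models set the verbal estimates:

* :func:`linear_clock_model` — a descriptive linear clock, e = a + g*d + eps
  with noise SD proportional to the expected estimate (constant coefficient
  of variation, i.e. the scalar property), plus optional symmetric outlier
  contamination for the outlier filter to catch;
* :func:`pacemaker_accumulator_model` — a mechanistic pacemaker/attentional
  gate: pulses at rate lambda are gated with probability p (attention on
  time), accumulated as a Poisson count, and read out against a calibration
  gate p_ref.  Multiplicative clock-rate noise dominates at long durations
  and yields the same scalar property.

Defaults are taken from the published group fits in :mod:`prostime.reference`
(16 participants, 10 repetitions per task x interval cell, cv = 0.2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference

__all__ = [
    "TASKS",
    "CONDITIONS",
    "NOMINAL_INTERVALS",
    "SOLVE_TASKS",
    "DesignSpec",
    "GenerativeParams",
    "PacemakerParams",
    "PerformanceParams",
    "CovariateTrend",
    "TrialRecord",
    "jitter_window",
    "generate_design",
    "generate_speed_schedule",
    "linear_clock_model",
    "pacemaker_accumulator_model",
    "attach_performance",
    "generate_covariates",
    "DEFAULT_CLOCK_PARAMS",
    "DEFAULT_PACEMAKER_PARAMS",
    "DEFAULT_PERFORMANCE_PARAMS",
    "DEFAULT_COVARIATE_TRENDS",
]

TASKS = ("look", "read", "solve_simple", "solve_hard")
CONDITIONS = ("sitting", "walking")
NOMINAL_INTERVALS = (15, 30, 60, 90, 120)
SOLVE_TASKS = ("solve_simple", "solve_hard")

TRIAL_COLUMNS = [
    "participant_id",
    "condition",
    "task",
    "session",
    "block",
    "nominal_s",
    "actual_s",
    "estimate_s",
]


def jitter_window(nominal: int, fraction: float = 0.10) -> tuple[int, int]:
    """Inclusive integer window of actual durations for a nominal interval.

    The boundary is rounded *outward* so that e.g. 15 s yields {13..17}
    (supports of size 5, 7, 13, 19, 25 for the default intervals).  The
    fraction is interpreted exactly (0.1 means one tenth), avoiding binary
    float artefacts at the window edges.
    """
    frac = Fraction(fraction).limit_denominator(10_000)
    lo = math.floor(nominal * (1 - frac))
    hi = math.ceil(nominal * (1 + frac))
    return lo, hi


@dataclass(frozen=True)
class DesignSpec:
    """Factorial design of one experiment.

    Defaults reproduce the study scale: 16 participants x 2 motor conditions
    x (4 tasks x 5 intervals x 10 reps) = 200 trials per condition per
    participant, in 20 blocks of 10 (two sessions of 10 blocks each).
    """

    n_participants: int = 16
    tasks: tuple[str, ...] = TASKS
    conditions: tuple[str, ...] = CONDITIONS
    nominal_intervals: tuple[int, ...] = NOMINAL_INTERVALS
    reps_per_cell: int = 10
    jitter_fraction: float = 0.10
    block_size: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.block_size != 2 * len(self.nominal_intervals):
            raise ValueError(
                "block_size must equal 2 x number of intervals so that every "
                f"block holds each interval twice; got block_size={self.block_size} "
                f"with {len(self.nominal_intervals)} intervals"
            )
        if (len(self.tasks) * self.reps_per_cell) % 2 != 0:
            raise ValueError("tasks x reps_per_cell must be even to fill blocks")

    @property
    def trials_per_condition(self) -> int:
        return len(self.tasks) * len(self.nominal_intervals) * self.reps_per_cell

    @property
    def n_blocks(self) -> int:
        return self.trials_per_condition // self.block_size


@dataclass(frozen=True)
class GenerativeParams:
    """Linear-clock parameters for one (task, condition) cell.

    offset (s) and gain map a true duration d to an expected estimate
    a + g*d, so the expected bias line has intercept a and slope g - 1.
    cv is the coefficient of variation of the estimate noise; a fraction
    outlier_rate of trials gets its noise SD multiplied by outlier_scale.
    """

    offset: float
    gain: float
    cv: float = 0.2
    outlier_rate: float = 0.02
    outlier_scale: float = 5.0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if not 0 <= self.outlier_rate < 0.2:
            raise ValueError("outlier_rate must be in [0, 0.2)")


@dataclass(frozen=True)
class PacemakerParams:
    """Pacemaker/attentional-gate parameters for one (task, condition) cell.

    base_rate: pulses per second; gate_prob: probability the attentional
    switch is closed (pulses reach the accumulator); reference_gate: gate
    probability assumed by the readout (calibration); gain_noise_sd: SD of
    the multiplicative per-trial clock-rate noise.
    """

    gate_prob: float
    reference_gate: float
    base_rate: float = 100.0
    gain_noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.gate_prob <= 1:
            raise ValueError("gate_prob must be in (0, 1]")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be > 0")
        if self.gain_noise_sd < 0:
            raise ValueError("gain_noise_sd must be >= 0")


@dataclass(frozen=True)
class PerformanceParams:
    """Bernoulli accuracy and log-normal response time for a math task."""

    accuracy: float
    rt_mean_s: float
    rt_cv: float = 0.4


@dataclass(frozen=True)
class CovariateTrend:
    """Linear per-block trend of a control covariate."""

    intercept: float
    slope_per_block: float
    noise_sd: float


@dataclass(frozen=True)
class TrialRecord:
    """One trial; the canonical in-memory container is a pandas frame with
    these fields as columns."""

    participant_id: int
    condition: str
    task: str
    session: int
    block: int
    nominal_s: int
    actual_s: int
    estimate_s: float = float("nan")
    correct: bool | None = None
    rt_s: float | None = None


def _caption_params() -> dict[tuple[str, str], GenerativeParams]:
    out = {}
    for (condition, task), fit in reference.BIAS_FIT_REFERENCE.items():
        out[(task, condition)] = GenerativeParams(
            offset=fit["intercept"], gain=1.0 + fit["slope"]
        )
    return out


DEFAULT_CLOCK_PARAMS: dict[tuple[str, str], GenerativeParams] = _caption_params()


def _default_pacemaker() -> dict[tuple[str, str], PacemakerParams]:
    # Gates scaled so the read task is near-veridical: p = (g / g_read) * p_read.
    base_read = {"sitting": 0.85, "walking": 0.80}
    out = {}
    for (task, condition), gp in DEFAULT_CLOCK_PARAMS.items():
        g_read = DEFAULT_CLOCK_PARAMS[("read", condition)].gain
        p_read = base_read[condition]
        out[(task, condition)] = PacemakerParams(
            gate_prob=min(1.0, gp.gain / g_read * p_read),
            reference_gate=p_read,
        )
    return out


DEFAULT_PACEMAKER_PARAMS: dict[tuple[str, str], PacemakerParams] = _default_pacemaker()

DEFAULT_PERFORMANCE_PARAMS: dict[tuple[str, str], PerformanceParams] = {
    (task, condition): PerformanceParams(p["accuracy"], p["rt_mean_s"])
    for (condition, task), p in reference.PERFORMANCE_REFERENCE.items()
}

DEFAULT_COVARIATE_TRENDS: dict[str, dict[str, CovariateTrend]] = {
    "sitting": {
        "fatigue": CovariateTrend(1.4, 0.01, 0.25),
        "tiredness": CovariateTrend(1.7, 0.13, 0.25),
        "temp_c": CovariateTrend(36.7, 0.0, 0.15),
    },
    "walking": {
        "fatigue": CovariateTrend(1.7, 0.15, 0.30),
        "tiredness": CovariateTrend(1.9, 0.16, 0.30),
        "temp_c": CovariateTrend(36.5, 0.0, 0.15),
    },
}


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """Lay out trials (estimates unset) for every participant and condition.

    Per participant and condition: each (task, interval) cell appears exactly
    ``reps_per_cell`` times; trials are grouped into blocks of ``block_size``
    with every nominal interval appearing exactly twice per block; the two
    halves of the block sequence are tagged as sessions 1 and 2.  Actual
    durations are drawn uniformly over the integer jitter window.
    Deterministic given ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n_blocks = spec.n_blocks
    blocks_per_session = max(1, n_blocks // 2)
    windows = {t: jitter_window(t, spec.jitter_fraction) for t in spec.nominal_intervals}

    rows: list[tuple] = []
    for pid in range(1, spec.n_participants + 1):
        for condition in spec.conditions:
            block_cells: list[list[tuple[int, str]]] = [[] for _ in range(n_blocks)]
            for nominal in spec.nominal_intervals:
                seq = np.repeat(spec.tasks, spec.reps_per_cell)
                rng.shuffle(seq)
                for b in range(n_blocks):
                    block_cells[b].append((nominal, seq[2 * b]))
                    block_cells[b].append((nominal, seq[2 * b + 1]))
            for b, cell in enumerate(block_cells):
                order = rng.permutation(len(cell))
                session = 1 + min(b // blocks_per_session, 1)
                for idx in order:
                    nominal, task = cell[idx]
                    lo, hi = windows[nominal]
                    actual = int(rng.integers(lo, hi + 1))
                    rows.append(
                        (pid, condition, task, session, b + 1, nominal, actual, np.nan)
                    )

    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def generate_speed_schedule(
    total_duration: float,
    seed: int | None = None,
    min_speed: float = 1.4,
    max_speed: float = 3.0,
    min_step: float = 0.4,
    max_step: float = 1.6,
    min_gap: float = 20.0,
    max_gap: float = 40.0,
) -> list[tuple[float, float]]:
    """Treadmill speed schedule: (onset_s, speed_kmh) change points.

    Speeds stay in [min_speed, max_speed]; consecutive absolute changes are
    in [min_step, max_step]; changes occur every [min_gap, max_gap] seconds.
    Metadata only — the schedule never feeds back into the estimates.
    """
    if total_duration < 0:
        raise ValueError("total_duration must be >= 0")
    if total_duration == 0:
        return []
    rng = np.random.default_rng(seed)
    speed = float(rng.uniform(min_speed, max_speed))
    schedule = [(0.0, speed)]
    t = float(rng.uniform(min_gap, max_gap))
    while t < total_duration:
        directions = []
        if max_speed - speed >= min_step:
            directions.append(1.0)
        if speed - min_speed >= min_step:
            directions.append(-1.0)
        direction = directions[int(rng.integers(len(directions)))]
        headroom = (max_speed - speed) if direction > 0 else (speed - min_speed)
        step = float(rng.uniform(min_step, min(max_step, headroom)))
        speed = speed + direction * step
        schedule.append((t, speed))
        t += float(rng.uniform(min_gap, max_gap))
    return schedule


def _require_cells(design: pd.DataFrame, params: Mapping[tuple[str, str], object]) -> None:
    present = set(zip(design["task"], design["condition"]))
    missing = sorted(present - set(params))
    if missing:
        raise KeyError(f"no generative parameters for cells: {missing}")


def linear_clock_model(
    design: pd.DataFrame,
    params: Mapping[tuple[str, str], GenerativeParams] | None = None,
    seed: int | None = None,
    noise: str = "gaussian",
    min_estimate: float = 1.0,
) -> pd.DataFrame:
    """Fill in verbal estimates with the descriptive linear-clock model.

    e = offset + gain * d + eps, where eps has zero mean and SD
    cv * (offset + gain * d); with probability outlier_rate the SD is
    multiplied by outlier_scale.  ``noise`` may be "gaussian" (default) or
    "lognormal" (right-skewed multiplicative noise with the same cv).
    Estimates are floored at ``min_estimate`` seconds.
    """
    if params is None:
        params = DEFAULT_CLOCK_PARAMS
    if noise not in ("gaussian", "lognormal"):
        raise ValueError(f"unknown noise law: {noise!r}")
    _require_cells(design, params)
    rng = np.random.default_rng(seed)

    out = design.copy()
    d = out["actual_s"].to_numpy(dtype=float)
    expected = np.empty(len(out))
    cv = np.empty(len(out))
    for (task, condition), p in params.items():
        mask = ((out["task"] == task) & (out["condition"] == condition)).to_numpy()
        if not mask.any():
            continue
        expected[mask] = p.offset + p.gain * d[mask]
        cell_cv = np.full(mask.sum(), p.cv)
        if p.outlier_rate > 0:
            contaminated = rng.random(mask.sum()) < p.outlier_rate
            cell_cv[contaminated] *= p.outlier_scale
        cv[mask] = cell_cv

    if noise == "gaussian":
        e = expected + rng.standard_normal(len(out)) * cv * expected
    else:
        sigma = np.sqrt(np.log1p(cv**2))
        e = expected * rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma)
    out["estimate_s"] = np.maximum(e, min_estimate)
    return out


def pacemaker_accumulator_model(
    design: pd.DataFrame,
    params: Mapping[tuple[str, str], PacemakerParams] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fill in estimates with the pacemaker/attentional-gate model.

    Per trial the clock rate is lambda_t = lambda * (1 + eta) with eta
    zero-mean Gaussian (SD gain_noise_sd), truncated strictly positive; the
    accumulator collects N ~ Poisson(p * lambda_t * d) pulses and the readout
    is e = N / (p_ref * lambda), floored at one pulse.
    """
    if params is None:
        params = DEFAULT_PACEMAKER_PARAMS
    _require_cells(design, params)
    for cell, p in params.items():
        if p.reference_gate == 0:
            raise ValueError(f"reference_gate must be non-zero (cell {cell})")
    rng = np.random.default_rng(seed)

    out = design.copy()
    d = out["actual_s"].to_numpy(dtype=float)
    e = np.empty(len(out))
    for (task, condition), p in params.items():
        mask = ((out["task"] == task) & (out["condition"] == condition)).to_numpy()
        if not mask.any():
            continue
        n = int(mask.sum())
        gain = 1.0 + rng.standard_normal(n) * p.gain_noise_sd
        gain = np.clip(gain, 1e-9, None)  # truncation: lambda_t > 0
        rate = p.gate_prob * p.base_rate * gain * d[mask]
        pulses = np.maximum(rng.poisson(rate), 1)
        e[mask] = pulses / (p.reference_gate * p.base_rate)
    out["estimate_s"] = e
    return out


def attach_performance(
    trials: pd.DataFrame,
    params: Mapping[tuple[str, str], PerformanceParams] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Add correctness and response-time columns for the math tasks.

    Correctness is Bernoulli with the configured accuracy; response times are
    log-normal with the configured mean and coefficient of variation.
    Non-math tasks get missing values.
    """
    if params is None:
        params = DEFAULT_PERFORMANCE_PARAMS
    rng = np.random.default_rng(seed)
    out = trials.copy()
    correct = np.full(len(out), np.nan)
    rt = np.full(len(out), np.nan)
    for (task, condition), p in params.items():
        mask = ((out["task"] == task) & (out["condition"] == condition)).to_numpy()
        if not mask.any():
            continue
        n = int(mask.sum())
        correct[mask] = (rng.random(n) < p.accuracy).astype(float)
        sigma = math.sqrt(math.log1p(p.rt_cv**2))
        mu = math.log(p.rt_mean_s) - sigma**2 / 2
        rt[mask] = rng.lognormal(mean=mu, sigma=sigma, size=n)
    out["correct"] = correct
    out["rt_s"] = rt
    return out


def generate_covariates(
    design: pd.DataFrame,
    trend_params: Mapping[str, Mapping[str, CovariateTrend]] | None = None,
    seed: int | None = None,
    rounded: bool = True,
) -> pd.DataFrame:
    """Per-block control covariates: fatigue, tiredness (Likert 1-7), body
    temperature (degC).

    One record per (participant, condition, session, within-session block).
    Latent values follow intercept + slope * (block - 1) + Gaussian noise;
    Likert outputs are clipped to [1, 7] and, when ``rounded``, reported on
    the integer scale; temperature is clipped to [35, 39].
    """
    if trend_params is None:
        trend_params = DEFAULT_COVARIATE_TRENDS
    rng = np.random.default_rng(seed)

    grid = (
        design[["participant_id", "condition", "session", "block"]]
        .drop_duplicates()
        .sort_values(["participant_id", "condition", "session", "block"])
        .reset_index(drop=True)
    )
    # within-session block index, 1-based
    first_block = grid.groupby(["participant_id", "condition", "session"])["block"].transform("min")
    grid["block_in_session"] = grid["block"] - first_block + 1

    def draw(var: str, clip_lo: float, clip_hi: float, likert: bool) -> np.ndarray:
        vals = np.empty(len(grid))
        for condition, trends in trend_params.items():
            mask = (grid["condition"] == condition).to_numpy()
            if not mask.any():
                continue
            tr = trends[var]
            b = grid.loc[mask, "block_in_session"].to_numpy(dtype=float)
            latent = tr.intercept + tr.slope_per_block * (b - 1)
            latent = latent + rng.standard_normal(mask.sum()) * tr.noise_sd
            vals[mask] = latent
        vals = np.clip(vals, clip_lo, clip_hi)
        if likert and rounded:
            vals = np.rint(vals)
        return vals

    out = grid.copy()
    out["fatigue"] = draw("fatigue", 1, 7, likert=True)
    out["tiredness"] = draw("tiredness", 1, 7, likert=True)
    out["temp_c"] = draw("temp_c", 35, 39, likert=False)
    return out
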