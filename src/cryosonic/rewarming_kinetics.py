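"""Rewarming kinetics: crossing times, windowed rates, ensembles, plans, stats.

Thermocouple logs from cryovials rewarmed in a 33 °C bath (with or without
ultrasound) are near-monotone warming traces with three regimes: a fast
frozen regime, a latent-heat plateau across the solid–fluid transition,
and a thawed approach to the bath temperature.  This module extracts the
quantities the rewarming study is built on:

* first upward crossing times of temperature thresholds (linear
  interpolation between samples),
* windowed rewarming rates in °C/min, conventionally over [−60, −40] °C
  (below the transition) and [−20, 5] °C (across it),
* total rewarming time from −65 °C to the 5 °C endpoint chosen to stay
  below cryoprotectant-toxicity temperatures,
* ensemble mean curves as time-at-temperature statistics (mean and SD of
  crossing times at each grid temperature, matching how replicate vials
  are averaged),
* instantaneous rate–temperature profiles and normalised curves,
* feedback-free exposure plans (ceil of the mean time to target), and
* the study's group comparisons (one-way ANOVA with Tukey HSD, two-tailed
  t-tests).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TemperatureTrace",
    "RewarmingEnsemble",
    "KineticsSummary",
    "ExposurePlan",
    "GroupComparisonResult",
    "ThresholdNotReachedError",
    "first_crossing_time",
    "window_rate",
    "total_rewarm_time",
    "ensemble_mean_curve",
    "normalized_curve",
    "instantaneous_rate",
    "plan_exposure",
    "summarise_kinetics",
    "compare_rate_groups",
    "compare_two_groups",
]


class ThresholdNotReachedError(ValueError):
    """Raised when a trace never reaches a requested temperature."""


@dataclass(frozen=True)
class TemperatureTrace:
    """A single-vial temperature log (time in s, temperature in °C)."""

    times_s: np.ndarray
    temperatures_c: np.ndarray
    power_w: float = 0.0
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        T = np.asarray(self.temperatures_c, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "temperatures_c", T)
        if t.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if t.shape != T.shape:
            raise ValueError("times and temperatures must have equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(T)):
            raise ValueError("temperatures must be finite")


def first_crossing_time(trace: TemperatureTrace, threshold_c: float) -> float:
    """Time of the first upward crossing of ``threshold_c``.

    Linear interpolation between the bracketing samples; if the trace
    starts at or above the threshold the start time is returned.  The
    first crossing is used (conservative under noise for warming traces).
    """
    T = trace.temperatures_c
    t = trace.times_s
    if T[0] >= threshold_c:
        return float(t[0])
    below = T[:-1] < threshold_c
    above = T[1:] >= threshold_c
    idx = np.flatnonzero(below & above)
    if idx.size == 0:
        raise ThresholdNotReachedError(
            f"trace never reaches {threshold_c} °C (max {T.max():.2f} °C)"
        )
    i = int(idx[0])
    frac = (threshold_c - T[i]) / (T[i + 1] - T[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def window_rate(trace: TemperatureTrace, t_lo_c: float, t_hi_c: float) -> float:
    """Mean rewarming rate in °C/min between two temperature thresholds."""
    if t_hi_c <= t_lo_c:
        raise ValueError("t_hi_c must exceed t_lo_c")
    t0 = first_crossing_time(trace, t_lo_c)
    t1 = first_crossing_time(trace, t_hi_c)
    if t1 <= t0:
        raise ValueError("zero or negative time difference across the window")
    return (t_hi_c - t_lo_c) / (t1 - t0) * 60.0


def total_rewarm_time(
    trace: TemperatureTrace, t_start_c: float = -65.0, t_end_c: float = 5.0
) -> float:
    """Total time in s to warm from ``t_start_c`` to ``t_end_c``."""
    t0 = first_crossing_time(trace, t_start_c)
    t1 = first_crossing_time(trace, t_end_c)
    return t1 - t0


@dataclass(frozen=True)
class RewarmingEnsemble:
    """Time-at-temperature statistics over replicate traces of one condition."""

    temperature_grid_c: np.ndarray
    mean_time_s: np.ndarray
    sd_time_s: np.ndarray
    per_trace_times_s: np.ndarray  # shape (n_traces, n_grid)
    power_w: float
    labels: dict = field(default_factory=dict)

    @property
    def n_traces(self) -> int:
        return self.per_trace_times_s.shape[0]


def default_temperature_grid(
    t_start_c: float = -65.0, t_end_c: float = 5.0, step_c: float = 0.5
) -> np.ndarray:
    n = int(round((t_end_c - t_start_c) / step_c))
    return t_start_c + step_c * np.arange(n + 1)


def ensemble_mean_curve(
    traces: Sequence[TemperatureTrace],
    temperature_grid_c: np.ndarray | None = None,
) -> RewarmingEnsemble:
    """Average replicate traces as time-at-temperature.

    For each grid temperature the first-crossing time of every trace is
    computed; the ensemble curve is the mean (and SD) of those times.
    Averaging in time at fixed temperature — rather than temperature at
    fixed time — keeps the latent-heat plateau aligned across replicates.
    """
    if len(traces) < 2:
        raise ValueError("an ensemble needs at least 2 traces")
    powers = {tr.power_w for tr in traces}
    if len(powers) > 1:
        raise ValueError("all traces in an ensemble must share the same power")
    if temperature_grid_c is None:
        temperature_grid_c = default_temperature_grid()
    grid = np.asarray(temperature_grid_c, dtype=float)
    times = np.empty((len(traces), grid.size))
    for i, tr in enumerate(traces):
        for j, T in enumerate(grid):
            times[i, j] = first_crossing_time(tr, T)  # raises if unreached
    return RewarmingEnsemble(
        temperature_grid_c=grid,
        mean_time_s=times.mean(axis=0),
        sd_time_s=times.std(axis=0, ddof=1) if len(traces) > 1 else np.zeros(grid.size),
        per_trace_times_s=times,
        power_w=traces[0].power_w,
        labels=dict(traces[0].labels),
    )


def normalized_curve(
    ensemble: RewarmingEnsemble, t_lo_c: float = -60.0, t_hi_c: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Mean curve with time rescaled so t(−60 °C) = 0 and t(5 °C) = 1.

    Returns ``(temperature_grid, normalized_time)`` restricted to the
    [t_lo_c, t_hi_c] span.  Normalisation exposes the shape of the
    rate–temperature profile independently of the absolute speed.
    """
    grid = ensemble.temperature_grid_c
    if grid.min() > t_lo_c or grid.max() < t_hi_c:
        raise ValueError("ensemble grid does not span the normalisation range")
    t_lo = float(np.interp(t_lo_c, grid, ensemble.mean_time_s))
    t_hi = float(np.interp(t_hi_c, grid, ensemble.mean_time_s))
    if t_hi <= t_lo:
        raise ValueError("degenerate time span for normalisation")
    mask = (grid >= t_lo_c) & (grid <= t_hi_c)
    return grid[mask], (ensemble.mean_time_s[mask] - t_lo) / (t_hi - t_lo)


def instantaneous_rate(
    ensemble: RewarmingEnsemble, smooth_window: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous rewarming rate dT/dt in °C/min on the temperature grid.

    Central differences of the mean time-at-temperature curve.  An optional
    odd-width moving average over the grid tames noise-amplified
    differentiation (off by default; width 5 is a reasonable choice for
    measured traces).
    """
    t = ensemble.mean_time_s
    if not np.all(np.diff(t) > 0):
        raise ValueError("mean curve must be strictly increasing in time")
    rate = 60.0 / np.gradient(t, ensemble.temperature_grid_c)
    if smooth_window is not None:
        if smooth_window < 1 or smooth_window % 2 == 0:
            raise ValueError("smooth_window must be a positive odd integer")
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(rate, pad, mode="edge")
        rate = np.convolve(padded, kernel, mode="valid")
    return ensemble.temperature_grid_c, rate


@dataclass(frozen=True)
class ExposurePlan:
    """A feedback-free sonication duration for one power condition."""

    power_w: float
    duration_s: int
    mean_time_s: float
    target_temperature_c: float
    source_labels: dict = field(default_factory=dict)


def plan_exposure(
    ensemble: RewarmingEnsemble, t_target_c: float = 5.0
) -> ExposurePlan:
    """Plan a fixed exposure: ceil of the mean time to reach the target.

    Rounding is upward to the whole second, matching an exposure timer with
    1 s resolution; undershooting the target temperature is the failure
    mode to avoid (residual ice), so the plan never rounds down.
    """
    grid = ensemble.temperature_grid_c
    if t_target_c > grid.max() or t_target_c < grid.min():
        raise ValueError("target temperature outside the ensemble grid")
    mean_t = float(
        np.interp(t_target_c, grid, ensemble.mean_time_s - ensemble.mean_time_s[0])
    )
    return ExposurePlan(
        power_w=ensemble.power_w,
        duration_s=int(math.ceil(mean_t)),
        mean_time_s=mean_t,
        target_temperature_c=t_target_c,
        source_labels=dict(ensemble.labels),
    )


@dataclass(frozen=True)
class KineticsSummary:
    """Windowed rates and total times for one condition (per trace and pooled)."""

    power_w: float
    low_t_rates_c_per_min: np.ndarray     # per trace, over [-60, -40] °C
    transition_rates_c_per_min: np.ndarray  # per trace, over [-20, 5] °C
    total_times_s: np.ndarray             # per trace, -65 -> 5 °C
    mean_low_t_rate: float
    sd_low_t_rate: float
    mean_transition_rate: float
    sd_transition_rate: float
    mean_total_time_s: float
    sd_total_time_s: float
    #: mean of per-trace overall rates (-65 -> 5 °C), °C/min
    mean_overall_rate: float
    #: span / mean total time, °C/min (differs slightly from the above)
    overall_rate_from_mean_time: float


def summarise_kinetics(
    traces: Sequence[TemperatureTrace],
    low_window: tuple[float, float] = (-60.0, -40.0),
    transition_window: tuple[float, float] = (-20.0, 5.0),
    t_start_c: float = -65.0,
    t_end_c: float = 5.0,
) -> KineticsSummary:
    """Extract the study's standard kinetics numbers from replicate traces."""
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    low = np.array([window_rate(tr, *low_window) for tr in traces])
    trans = np.array([window_rate(tr, *transition_window) for tr in traces])
    tot = np.array([total_rewarm_time(tr, t_start_c, t_end_c) for tr in traces])
    span = t_end_c - t_start_c
    overall = span / tot * 60.0
    sd = lambda x: float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return KineticsSummary(
        power_w=traces[0].power_w,
        low_t_rates_c_per_min=low,
        transition_rates_c_per_min=trans,
        total_times_s=tot,
        mean_low_t_rate=float(low.mean()),
        sd_low_t_rate=sd(low),
        mean_transition_rate=float(trans.mean()),
        sd_transition_rate=sd(trans),
        mean_total_time_s=float(tot.mean()),
        sd_total_time_s=sd(tot),
        mean_overall_rate=float(overall.mean()),
        overall_rate_from_mean_time=float(span / tot.mean() * 60.0),
    )


@dataclass(frozen=True)
class GroupComparisonResult:
    """Outcome of a one-way ANOVA or a two-sample t-test."""

    test_name: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = None
    degenerate: bool = False


def compare_rate_groups(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> GroupComparisonResult:
    """One-way ANOVA across labelled groups, with Tukey HSD pairwise follow-up.

    Pairwise comparisons (all group pairs, family-wise adjusted) are
    computed when the omnibus test is significant at ``alpha``.  If every
    observation is identical the F statistic is undefined; this degenerate
    case is flagged with F = 0, p = 1 rather than raising.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    allvals = np.concatenate(arrays)
    if np.all(allvals == allvals[0]):
        return GroupComparisonResult("one-way ANOVA", 0.0, 1.0, None, degenerate=True)
    f, p = sps.f_oneway(*arrays)
    pairwise = None
    if p < alpha:
        res = sps.tukey_hsd(*arrays)
        rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                ci = res.confidence_interval()
                rows.append(
                    {
                        "group_a": names[i],
                        "group_b": names[j],
                        "mean_difference": float(arrays[i].mean() - arrays[j].mean()),
                        "p_adj": float(res.pvalue[i, j]),
                        "ci_low": float(ci.low[i, j]),
                        "ci_high": float(ci.high[i, j]),
                    }
                )
        pairwise = pd.DataFrame(rows)
    return GroupComparisonResult("one-way ANOVA", float(f), float(p), pairwise)


def compare_two_groups(
    a: Sequence[float], b: Sequence[float]
) -> GroupComparisonResult:
    """Two-tailed two-sample (equal-variance) t-test."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(x) == 0 and np.var(y) == 0:
        if x.mean() == y.mean():
            return GroupComparisonResult("t-test", 0.0, 1.0, degenerate=True)
        warnings.warn("degenerate zero-variance groups with distinct means; p -> 0")
        return GroupComparisonResult("t-test", math.inf, 0.0, degenerate=True)
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return GroupComparisonResult("t-test", float(t), float(p))
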