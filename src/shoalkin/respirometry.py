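"""Closed-respirometry metabolic rates and Q10 thermal sensitivity.

Oxygen concentration in a sealed chamber declines as the fish consume it;
the decline rate (mg O2 L^-1 h^-1) is the shoal-level oxygen consumption
rate MO2.  From a trace sampled every ~60 s with phase labels this module
estimates:

* resting routine MO2 — the least-squares slope over the final portion of
  the pre-exercise rest phase (the early acclimation transient is skipped);
* peak recovery MO2 — the largest slope of a short window slid across the
  post-exercise recovery phase (excess post-exercise oxygen consumption is
  maximal at recovery onset);
* factorial MO2 — peak / resting, an aerobic-scope proxy; and
* Q10 — the factor by which a rate changes per 10 deg C,
  Q10 = (K2/K1)^(10/(T2-T1)).

Rates are deliberately not mass- or volume-adjusted: comparisons are made
within a stage across temperatures, where the chamber and the animals are
the same.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "OxygenTrace",
    "SlopeFit",
    "MetabolicRecord",
    "Q10Inputs",
    "resting_mo2",
    "peak_recovery_mo2",
    "factorial_mo2",
    "q10",
    "q10_value",
    "analyze_trace",
    "stage_q10_table",
]

SECONDS_PER_HOUR = 3600.0


@dataclass
class OxygenTrace:
    """Timestamped oxygen concentration series for one trial.

    ``phase`` labels each sample 'rest', 'recovery' or 'reset' (a re-aeration
    sample; excluded from every slope window).  Rest precedes recovery.
    """

    times_s: np.ndarray
    o2_mg_per_l: np.ndarray
    phase: np.ndarray
    temperature_c: float
    shoal_id: str | None = None
    stage: str | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.o2_mg_per_l = np.asarray(self.o2_mg_per_l, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (self.times_s.shape == self.o2_mg_per_l.shape == self.phase.shape):
            raise ValueError("times, o2 and phase must have equal length")
        if self.times_s.size >= 2 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.o2_mg_per_l <= 0):
            raise ValueError("oxygen concentrations must be positive")
        bad = set(np.unique(self.phase)) - {"rest", "recovery", "reset"}
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")


@dataclass(frozen=True)
class SlopeFit:
    """A fitted decline rate with its diagnostics."""

    rate: float  # mg O2 / L / h, >= 0
    r_squared: float
    t_start_s: float
    t_stop_s: float
    n_samples: int


@dataclass
class MetabolicRecord:
    """Per-shoal metabolic summary."""

    mo2_rest: float
    mo2_peak: float
    factorial_mo2: float
    rest_fit: SlopeFit | None = None
    peak_fit: SlopeFit | None = None


@dataclass(frozen=True)
class Q10Inputs:
    """Mean rates K1, K2 at temperatures T1, T2 (deg C)."""

    k1: float
    k2: float
    t1: float
    t2: float

    def __post_init__(self) -> None:
        if not (self.k1 > 0 and self.k2 > 0):
            raise ValueError("rates must be positive")
        if self.t1 == self.t2:
            raise ValueError("temperatures must differ")


def _ols(t_s: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope (per hour) and r^2 of an ordinary least-squares line."""
    t = (t_s - t_s.mean()) / SECONDS_PER_HOUR
    yc = y - y.mean()
    sxx = float(np.dot(t, t))
    slope = float(np.dot(t, yc)) / sxx
    ss_tot = float(np.dot(yc, yc))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.dot(yc - slope * t, yc - slope * t)) / ss_tot
    return slope, r2


def resting_mo2(trace: OxygenTrace, window_min: float = 30.0) -> SlopeFit:
    """Resting routine MO2 from the final ``window_min`` of the rest phase.

    The magnitude of the OLS slope over that window, in mg O2 L^-1 h^-1.
    A rising trace (positive slope) is clamped to zero with a warning.
    """
    mask = trace.phase == "rest"
    if mask.sum() < 3:
        raise ValueError("rest phase has too few samples")
    t = trace.times_s[mask]
    y = trace.o2_mg_per_l[mask]
    t_end = t[-1]
    sel = t >= t_end - window_min * 60.0
    if sel.sum() < 3:
        raise ValueError("rest window contains too few samples")
    span = (t[sel][-1] - t[sel][0]) / 60.0
    if span + 1e-9 < 0.5 * window_min:
        raise ValueError("rest phase shorter than the requested window")
    slope, r2 = _ols(t[sel], y[sel])
    if slope > 0:
        warnings.warn("oxygen rising during rest window; rate clamped at 0")
        rate = 0.0
    else:
        rate = -slope
    return SlopeFit(rate, r2, float(t[sel][0]), float(t[sel][-1]), int(sel.sum()))


def peak_recovery_mo2(trace: OxygenTrace, window_min: float = 3.0) -> SlopeFit:
    """Peak MO2 during recovery: the max slope of a sliding window.

    A window of ``window_min`` minutes is slid sample-by-sample across the
    recovery phase; each window's decline rate is the magnitude of its OLS
    slope and the largest is returned.  Reset-labeled samples break the
    phase into runs and are excluded from every window.  The short default
    window resolves the early-recovery peak; because the underlying rate
    decays monotonically after exercise, any finite window averages it down,
    so the estimate bounds the true peak from below.
    """
    mask = trace.phase == "recovery"
    if mask.sum() < 2:
        raise ValueError("recovery phase has too few samples")
    idx = np.nonzero(mask)[0]
    # contiguous runs of recovery samples (resets split them)
    run_breaks = np.nonzero(np.diff(idx) > 1)[0] + 1
    runs = np.split(idx, run_breaks)
    # the last rest sample is the chamber state at recovery onset: the drop
    # to the first recovery sample is recovery consumption, so include it
    # (never across a reset, whose re-aeration jump is not consumption)
    first = runs[0]
    if first[0] > 0 and trace.phase[first[0] - 1] == "rest":
        runs[0] = np.concatenate([[first[0] - 1], first])
    dt = np.median(np.diff(trace.times_s))
    k = int(round(window_min * 60.0 / dt)) + 1  # samples per window
    k = max(k, 2)
    best: SlopeFit | None = None
    for run in runs:
        if run.size < k:
            continue
        t = trace.times_s[run]
        y = trace.o2_mg_per_l[run]
        for i in range(run.size - k + 1):
            slope, r2 = _ols(t[i : i + k], y[i : i + k])
            rate = max(0.0, -slope)
            if best is None or rate > best.rate:
                best = SlopeFit(rate, r2, float(t[i]), float(t[i + k - 1]), k)
    if best is None:
        raise ValueError("recovery phase shorter than the requested window")
    return best


def factorial_mo2(rest: float, peak: float) -> float:
    """Factorial MO2 = peak / rest; NaN with a warning when rest is zero."""
    if rest == 0:
        warnings.warn("resting rate is zero; factorial MO2 undefined")
        return np.nan
    return peak / rest


def q10_value(k1: float, k2: float, t1: float, t2: float) -> float:
    """Q10 = (K2/K1)^(10/(T2-T1))."""
    return q10(Q10Inputs(k1, k2, t1, t2))


def q10(inputs: Q10Inputs) -> float:
    return float((inputs.k2 / inputs.k1) ** (10.0 / (inputs.t2 - inputs.t1)))


def analyze_trace(
    trace: OxygenTrace,
    rest_window_min: float = 30.0,
    peak_window_min: float = 3.0,
) -> MetabolicRecord:
    """Resting, peak and factorial MO2 for one trace."""
    rest = resting_mo2(trace, rest_window_min)
    peak = peak_recovery_mo2(trace, peak_window_min)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fact = factorial_mo2(rest.rate, peak.rate)
    return MetabolicRecord(rest.rate, peak.rate, fact, rest, peak)


def stage_q10_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-stage Q10 for resting and peak rates between two temperatures.

    ``records`` is tidy with one row per shoal and columns ``stage``,
    ``temperature_c`` (nominal treatment), ``mo2_rest``, ``mo2_peak`` and
    optionally ``recorded_temp_c`` (daily-mean measured temperature).  K1/K2
    are the unweighted means of per-shoal rates within (stage, low temp) and
    (stage, high temp); T1/T2 are the mean recorded temperatures when
    provided, otherwise the nominal treatments.  Stages with an empty
    temperature cell yield NaN with a warning.
    """
    required = {"stage", "temperature_c", "mo2_rest", "mo2_peak"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records table lacks columns: {sorted(missing)}")
    temps = sorted(records["temperature_c"].unique())
    if len(temps) != 2:
        raise ValueError("Q10 needs exactly two temperature treatments")
    t_low, t_high = temps
    rows = []
    for stage, grp in records.groupby("stage", sort=False):
        lo = grp[grp["temperature_c"] == t_low]
        hi = grp[grp["temperature_c"] == t_high]
        if "recorded_temp_c" in grp.columns and grp["recorded_temp_c"].notna().all():
            t1 = float(lo["recorded_temp_c"].mean()) if len(lo) else t_low
            t2 = float(hi["recorded_temp_c"].mean()) if len(hi) else t_high
        else:
            t1, t2 = float(t_low), float(t_high)
        for rate_type, col in (("rest", "mo2_rest"), ("peak", "mo2_peak")):
            if len(lo) == 0 or len(hi) == 0:
                warnings.warn(f"stage {stage!r} has an empty temperature cell")
                value = np.nan
                k1 = k2 = np.nan
            else:
                k1 = float(lo[col].mean())
                k2 = float(hi[col].mean())
                value = q10_value(k1, k2, t1, t2)
            rows.append(
                {
                    "stage": stage,
                    "rate_type": rate_type,
                    "k1": k1,
                    "k2": k2,
                    "t1_c": t1,
                    "t2_c": t2,
                    "q10": value,
                    "n_low": len(lo),
                    "n_high": len(hi),
                }
            )
    return pd.DataFrame(rows)
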