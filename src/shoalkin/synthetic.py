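"""Synthetic shoaling data with known ground truth.

Generates the three raw-data kinds the analysis consumes — digitized fish
midlines, shoal trajectories, and chamber oxygen traces — from fully
specified parametric models, so that every estimator can be validated by
parameter recovery.  A whole multi-stage, two-temperature study can be
generated in one call with injectable stage and temperature effects.

Models
------
* Midlines follow a kinematically prescribed travelling wave on an
  inextensible body: lateral displacement
  ``y(s, t) = A(s) sin(2 pi (f t - s / lambda))`` with amplitude envelope
  ``A(s) = head_amp + (tail_amp - head_amp) s**e`` over arc length
  ``s in [0, 1]`` BL.  Points are equally spaced along the body and the
  streamwise coordinate is reconstructed so consecutive-point chord lengths
  are constant (the body does not stretch).  No hydrodynamics: the study's
  estimators measure kinematics, not forces.
* Shoal members hold noisy stations on a streamwise line whose mean pairwise
  distance equals the target separation; adjacent streamwise ranks swap at
  Poisson-distributed event times.
* Oxygen declines linearly at the resting rate during the rest phase and at
  ``rest + (peak - rest) exp(-t / tau)`` during recovery (an exponentially
  decaying excess post-exercise consumption, maximal at recovery onset).
  If the concentration would fall below a floor the chamber is re-aerated
  and the sample labeled 'reset'.

Every generator is deterministic given (params, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd

from .kinematics import MidlineSequence
from .respirometry import OxygenTrace
from .shoal import ShoalTrajectory

__all__ = [
    "WaveModelParams",
    "ShoalSimParams",
    "RespoSimParams",
    "SyntheticTruth",
    "StageDesign",
    "StudyDesign",
    "StudyBundle",
    "generate_midline_sequence",
    "generate_shoal_trajectory",
    "generate_oxygen_trace",
    "generate_study",
    "default_study_design",
    "zero_effect_design",
]

STAGE_PREFIX = {"larva": "L", "juvenile": "J", "adult": "A"}


class ParameterError(ValueError):
    """A generator parameter set violates its invariants."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveModelParams:
    """Travelling-wave midline model parameters (lengths in BL)."""

    tbf_hz: float = 10.0
    wavelength_bl: float = 0.95
    head_amp_bl: float = 0.02
    tail_amp_bl: float = 0.08
    envelope_exponent: float = 2.0
    body_length_mm: float = 36.0
    frame_rate: float = 1000.0
    n_points: int = 200
    noise_sd_bl: float = 0.0
    phase0: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tbf_hz > 0:
            raise ParameterError("tbf_hz must be positive")
        if not self.wavelength_bl > 0:
            raise ParameterError("wavelength_bl must be positive")
        if not (0 <= self.head_amp_bl <= self.tail_amp_bl):
            raise ParameterError("need 0 <= head_amp_bl <= tail_amp_bl")
        if not self.envelope_exponent > 0:
            raise ParameterError("envelope_exponent must be positive")
        if self.n_points < 11:
            raise ParameterError(
                "n_points must be >= 11 (three-point curvature at 5% BL "
                "spacing needs interior stations)"
            )
        if not self.frame_rate > 2.0 * self.tbf_hz:
            raise ParameterError("frame_rate must exceed 2 * tbf_hz (Nyquist)")
        if not self.body_length_mm > 0:
            raise ParameterError("body_length_mm must be positive")
        if self.noise_sd_bl < 0:
            raise ParameterError("noise_sd_bl must be non-negative")


@dataclass(frozen=True)
class ShoalSimParams:
    """Station-holding shoal simulation parameters."""

    n_fish: int = 5
    mean_sep_bl: float = 2.0
    switch_rate_per_s: float = 0.1
    flow_speed_bl_s: float = 2.0
    duration_s: float = 60.0
    sample_hz: float = 25.0
    jitter_sd_bl: float = 0.0
    body_length_mm: float = 36.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fish < 2:
            raise ParameterError("n_fish must be >= 2")
        if not self.mean_sep_bl > 0:
            raise ParameterError("mean_sep_bl must be positive")
        if self.switch_rate_per_s < 0:
            raise ParameterError("switch_rate_per_s must be >= 0")
        if self.jitter_sd_bl < 0:
            raise ParameterError("jitter_sd_bl must be >= 0")
        if int(round(self.duration_s * self.sample_hz)) + 1 < 2:
            raise ParameterError("duration_s * sample_hz yields fewer than 2 samples")


@dataclass(frozen=True)
class RespoSimParams:
    """Closed-respirometry trace simulation parameters.

    Slopes are concentration decline rates in mg O2 L^-1 h^-1 for the whole
    shoal; ``recovery_decay_min`` is the time constant of the excess
    post-exercise consumption decay.
    """

    resting_slope: float = 1.0
    peak_slope: float = 2.5
    recovery_decay_min: float = 15.0
    o2_start: float = 8.0
    sample_period_s: float = 60.0
    rest_duration_min: float = 60.0
    recovery_duration_min: float = 120.0
    noise_sd: float = 0.0
    temperature_c: float = 28.0
    o2_floor: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.resting_slope > 0:
            raise ParameterError("resting_slope must be positive")
        if not self.peak_slope >= self.resting_slope:
            raise ParameterError("peak_slope must be >= resting_slope")
        if not self.recovery_decay_min > 0:
            raise ParameterError("recovery_decay_min must be positive")
        if not self.o2_start > self.o2_floor:
            raise ParameterError("o2_start must exceed the re-aeration floor")
        if self.recovery_duration_min < 120.0 - 1e-9:
            raise ParameterError("recovery_duration_min must be >= 120")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth serialized alongside every generated dataset."""

    kind: str
    params: dict[str, Any]
    derived: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {"kind": self.kind, "params": dict(self.params), "derived": dict(self.derived)}


# ---------------------------------------------------------------------------
# midline generator
# ---------------------------------------------------------------------------

def _envelope(s: np.ndarray, p: WaveModelParams) -> np.ndarray:
    return p.head_amp_bl + (p.tail_amp_bl - p.head_amp_bl) * s ** p.envelope_exponent


def _wave_derivatives(s: np.ndarray, phase: np.ndarray, p: WaveModelParams):
    """Analytic y'(s), y''(s) of the wave at given phases (s in BL units)."""
    e = p.envelope_exponent
    dA = p.tail_amp_bl - p.head_amp_bl
    A = p.head_amp_bl + dA * s ** e
    A1 = dA * e * s ** (e - 1.0)
    A2 = dA * e * (e - 1.0) * s ** (e - 2.0) if e != 1.0 else np.zeros_like(s)
    k = -2.0 * np.pi / p.wavelength_bl  # d(phase)/ds
    sin, cos = np.sin(phase), np.cos(phase)
    y1 = A1 * sin + A * k * cos
    y2 = A2 * sin + 2.0 * A1 * k * cos - A * k * k * sin
    return y1, y2


def analytic_max_curvature(p: WaveModelParams, n_s: int = 2001, n_t: int = 256) -> float:
    """Maximum curvature (1/BL) of the noiseless wave, from closed-form
    derivatives on a dense (s, phase) grid.

    With arc-length parameterization the curvature of the planar curve is
    ``|y''| / sqrt(1 - y'^2)``.
    """
    if p.tail_amp_bl == 0.0:
        return 0.0
    s = np.linspace(1e-6, 1.0, n_s)
    best = 0.0
    for ph0 in np.linspace(0.0, 2.0 * np.pi, n_t, endpoint=False):
        phase = ph0 - 2.0 * np.pi * s / p.wavelength_bl
        y1, y2 = _wave_derivatives(s, phase, p)
        denom = np.sqrt(np.clip(1.0 - y1 * y1, 1e-12, None))
        best = max(best, float(np.max(np.abs(y2) / denom)))
    return best


def _max_slope(p: WaveModelParams) -> float:
    s = np.linspace(1e-6, 1.0, 2001)
    m = 0.0
    for ph0 in np.linspace(0.0, 2.0 * np.pi, 64, endpoint=False):
        phase = ph0 - 2.0 * np.pi * s / p.wavelength_bl
        y1, _ = _wave_derivatives(s, phase, p)
        m = max(m, float(np.max(np.abs(y1))))
    return m


def generate_midline_sequence(
    params: WaveModelParams, n_cycles: int = 1, fish_id: str = "fish"
) -> tuple[MidlineSequence, SyntheticTruth]:
    """Midlines of one fish over ``n_cycles`` complete tail-beat cycles.

    The sequence spans exactly ``n_cycles / tbf`` seconds (so the frame
    count is ``round(n_cycles * frame_rate / tbf) + 1``); the head is point
    0 at x = 0 and the body extends toward +x while the fish faces the
    oncoming flow (-x).  Positional jitter is i.i.d. Gaussian per point and
    coordinate.
    """
    if n_cycles < 1:
        raise ParameterError("n_cycles must be >= 1")
    if params.tail_amp_bl > 0 and _max_slope(params) >= 0.995:
        raise ParameterError(
            "amplitude/wavelength combination gives lateral slope >= 1; "
            "not realizable as an inextensible body"
        )
    n_frames = int(round(n_cycles * params.frame_rate / params.tbf_hz)) + 1
    times = np.arange(n_frames) / params.frame_rate
    s = np.linspace(0.0, 1.0, params.n_points)
    phase = (
        2.0 * np.pi * (params.tbf_hz * times[:, None] - s[None, :] / params.wavelength_bl)
        + params.phase0
    )
    y = _envelope(s, params)[None, :] * np.sin(phase)  # (F, P) in BL
    ds = 1.0 / (params.n_points - 1)
    dy = np.diff(y, axis=1)
    dx = np.sqrt(np.maximum(ds * ds - dy * dy, 0.0))
    x = np.concatenate([np.zeros((n_frames, 1)), np.cumsum(dx, axis=1)], axis=1)
    coords = np.stack([x, y], axis=2) * params.body_length_mm
    if params.noise_sd_bl > 0:
        rng = np.random.default_rng(params.seed)
        coords = coords + rng.normal(
            0.0, params.noise_sd_bl * params.body_length_mm, size=coords.shape
        )
    seq = MidlineSequence(
        fish_id=fish_id,
        times=times,
        coords=coords,
        body_length_mm=params.body_length_mm,
        frame_rate=params.frame_rate,
    )
    env = _envelope(s, params)
    truth = SyntheticTruth(
        kind="midline",
        params=asdict(params),
        derived={
            "n_cycles": n_cycles,
            "n_frames": n_frames,
            "wave_speed_bl_s": params.tbf_hz * params.wavelength_bl,
            "max_curvature_per_bl": analytic_max_curvature(params),
            # amplitude of the 5-point head/tail signals the estimator uses
            "head_amp5_bl": float(env[:5].mean()),
            "tail_amp5_bl": float(env[-5:].mean()),
        },
    )
    return seq, truth


# ---------------------------------------------------------------------------
# shoal trajectory generator
# ---------------------------------------------------------------------------

def generate_shoal_trajectory(
    params: ShoalSimParams,
) -> tuple[ShoalTrajectory, SyntheticTruth]:
    """Station-holding shoal with Poisson adjacent-rank switches.

    Fish occupy stations on a streamwise line with spacing chosen so the
    mean pairwise distance equals ``mean_sep_bl`` (for equally spaced
    collinear stations the mean pairwise distance is spacing * (n+1)/3).
    Switch events arrive at Poisson times; each swaps the stations of one
    uniformly chosen adjacent-rank pair, completed within one sample step.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_fish
    bl = params.body_length_mm
    spacing_bl = 3.0 * params.mean_sep_bl / (n + 1)
    stations_mm = np.arange(n) * spacing_bl * bl
    n_samples = int(round(params.duration_s * params.sample_hz)) + 1
    times = np.arange(n_samples) / params.sample_hz

    n_events = rng.poisson(params.switch_rate_per_s * params.duration_s)
    event_times = np.sort(rng.uniform(0.0, params.duration_s, size=n_events))
    event_ranks = rng.integers(0, n - 1, size=n_events)

    station_of_fish = np.arange(n)  # fish i sits at stations_mm[station_of_fish[i]]
    positions = np.zeros((n_samples, n, 2))
    ev = 0
    for k, t in enumerate(times):
        while ev < n_events and event_times[ev] <= t:
            r = event_ranks[ev]
            # fish currently occupying stations r and r+1 swap
            i = int(np.nonzero(station_of_fish == r)[0][0])
            j = int(np.nonzero(station_of_fish == r + 1)[0][0])
            station_of_fish[i], station_of_fish[j] = r + 1, r
            ev += 1
        positions[k, :, 0] = stations_mm[station_of_fish]
    if params.jitter_sd_bl > 0:
        positions = positions + rng.normal(
            0.0, params.jitter_sd_bl * bl, size=positions.shape
        )
    traj = ShoalTrajectory(
        times=times,
        positions=positions,
        body_lengths_mm=np.full(n, bl),
        flow_axis=np.array([1.0, 0.0]),
    )
    truth = SyntheticTruth(
        kind="trajectory",
        params=asdict(params),
        derived={
            "realized_switches": int(n_events),
            "station_spacing_bl": spacing_bl,
            "mean_sep_bl": params.mean_sep_bl,
        },
    )
    return traj, truth


# ---------------------------------------------------------------------------
# oxygen trace generator
# ---------------------------------------------------------------------------

def _cumulative_consumption(t_s: np.ndarray, p: RespoSimParams) -> np.ndarray:
    """Integrated O2 consumed (mg/L) since t=0 under the two-phase rate law."""
    rest_end = p.rest_duration_min * 60.0
    t_h = np.minimum(t_s, rest_end) / 3600.0
    c = p.resting_slope * t_h
    rec = np.maximum(t_s - rest_end, 0.0) / 3600.0  # hours into recovery
    tau_h = p.recovery_decay_min / 60.0
    c = c + p.resting_slope * rec + (p.peak_slope - p.resting_slope) * tau_h * (
        1.0 - np.exp(-rec / tau_h)
    )
    return c


def instantaneous_recovery_rate(t_min: float, p: RespoSimParams) -> float:
    """Closed-form consumption rate (mg O2/L/h) ``t_min`` into recovery."""
    return p.resting_slope + (p.peak_slope - p.resting_slope) * math.exp(
        -t_min / p.recovery_decay_min
    )


def generate_oxygen_trace(
    params: RespoSimParams, shoal_id: str | None = None, stage: str | None = None
) -> tuple[OxygenTrace, SyntheticTruth]:
    """Two-phase oxygen trace: linear rest decline, decaying-EPOC recovery.

    The instantaneous decline rate is ``resting_slope`` during rest and
    ``resting + (peak - resting) exp(-t/tau)`` during recovery (maximal at
    recovery onset).  When the concentration would cross the floor the
    chamber is re-aerated back to ``o2_start`` and that sample is labeled
    'reset' so slope fitting can exclude it.
    """
    p = params
    rest_end = p.rest_duration_min * 60.0
    total = rest_end + p.recovery_duration_min * 60.0
    times = np.arange(0.0, total + 0.5 * p.sample_period_s, p.sample_period_s)
    consumed = _cumulative_consumption(times, p)
    values = np.empty_like(times)
    phase = np.empty(times.shape, dtype=object)
    offset = 0.0
    n_resets = 0
    for k, t in enumerate(times):
        v = p.o2_start - (consumed[k] - offset)
        lab = "rest" if t <= rest_end else "recovery"
        if v <= p.o2_floor:
            offset = consumed[k]
            v = p.o2_start
            lab = "reset"
            n_resets += 1
        values[k] = v
        phase[k] = lab
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        values = values + rng.normal(0.0, p.noise_sd, size=values.shape)
        values = np.maximum(values, 1e-3)
    trace = OxygenTrace(
        times_s=times,
        o2_mg_per_l=values,
        phase=phase,
        temperature_c=p.temperature_c,
        shoal_id=shoal_id,
        stage=stage,
    )
    truth = SyntheticTruth(
        kind="oxygen",
        params=asdict(p),
        derived={
            "resting_slope": p.resting_slope,
            "peak_slope": p.peak_slope,
            "n_resets": n_resets,
        },
    )
    return trace, truth


# ---------------------------------------------------------------------------
# whole-study generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageDesign:
    """Injectable per-stage ground truth for the study generator.

    ``tbf_base_hz`` applies at 1.5 BL/s and the low temperature; TBF grows
    by ``tbf_speed_slope`` per BL/s of flow speed and by the factor
    ``tbf_temp_factor`` at the high temperature.  Metabolic rates at the
    high temperature are the low-temperature rates times the respective
    ``*_temp_ratio`` (a ratio r over a 4 deg C interval corresponds to
    Q10 = r^2.5).
    """

    name: str
    speeds_bl_s: tuple[float, ...]
    body_length_mm: float
    tbf_base_hz: float
    tbf_speed_slope: float = 1.0
    tbf_temp_factor: float = 1.05
    wavelength_bl: float = 0.95
    head_amp_bl: float = 0.02
    tail_amp_bl: float = 0.08
    mean_sep_bl: float = 2.0
    sep_temp_factor: float = 1.0
    switch_rate_per_s: float = 0.15
    resting_rate: float = 1.0
    peak_rate: float = 2.5
    resting_temp_ratio: float = 1.32
    peak_temp_ratio: float = 1.32


@dataclass(frozen=True)
class StudyDesign:
    """Experiment layout: stages x temperatures x numbered replicate shoals.

    Odd-numbered shoals are assigned to the high temperature, even-numbered
    to the low, matching the alternating treatment layout of the emulated
    design; ``missing_shoals`` lists (stage, number) cells absent from the
    study.
    """

    stages: tuple[StageDesign, ...]
    temp_low_c: float = 28.0
    temp_high_c: float = 32.0
    shoals_per_stage: int = 10
    missing_shoals: tuple[tuple[str, int], ...] = (("juvenile", 9),)
    n_fish: int = 5
    frame_rate: float = 250.0
    n_cycles: int = 2
    midline_noise_sd_bl: float = 0.003
    traj_duration_s: float = 60.0
    traj_sample_hz: float = 25.0
    traj_jitter_sd_bl: float = 0.01
    shoal_cv: float = 0.04
    fish_tbf_sd_hz: float = 0.3
    o2_start: float = 8.0
    o2_noise_sd: float = 0.01
    recovery_decay_min: float = 15.0
    rest_duration_min: float = 60.0
    recovery_duration_min: float = 120.0
    temp_record_sd_c: float = 0.2


def default_study_design() -> StudyDesign:
    """Three stages x two temperatures with ontogeny and warming effects.

    Injected directions: mean separation and TBF decrease from larvae to
    juveniles to adults; switch rate doubles over ontogeny; resting-rate
    thermal ratios correspond to Q10 of about 2 in larvae and adults but a
    strongly elevated juvenile value; peak-rate ratios give low larval and
    juvenile but typical adult thermal sensitivity.
    """
    # over the 4 deg C interval a Q10 of q corresponds to a ratio q**0.4
    stages = (
        StageDesign(
            name="larva",
            speeds_bl_s=(1.5, 2.6, 3.0, 4.0, 5.0),
            body_length_mm=8.2,
            tbf_base_hz=22.0,
            tbf_temp_factor=1.10,
            wavelength_bl=0.60,
            head_amp_bl=0.04,
            tail_amp_bl=0.08,
            mean_sep_bl=3.0,
            switch_rate_per_s=0.10,
            resting_rate=0.6,
            peak_rate=1.5,
            resting_temp_ratio=1.96 ** 0.4,
            peak_temp_ratio=1.03 ** 0.4,
        ),
        StageDesign(
            name="juvenile",
            speeds_bl_s=(1.5, 2.0, 3.0, 4.0, 5.0),
            body_length_mm=13.9,
            tbf_base_hz=14.0,
            tbf_temp_factor=1.05,
            wavelength_bl=0.75,
            head_amp_bl=0.03,
            tail_amp_bl=0.08,
            mean_sep_bl=1.8,
            switch_rate_per_s=0.15,
            resting_rate=0.8,
            peak_rate=2.4,
            resting_temp_ratio=9.98 ** 0.4,
            peak_temp_ratio=1.37 ** 0.4,
        ),
        StageDesign(
            name="adult",
            speeds_bl_s=(1.0, 1.5, 2.0, 3.0, 4.0, 5.0),
            body_length_mm=36.4,
            tbf_base_hz=7.0,
            tbf_temp_factor=1.02,
            wavelength_bl=0.95,
            head_amp_bl=0.02,
            tail_amp_bl=0.08,
            mean_sep_bl=1.0,
            switch_rate_per_s=0.20,
            resting_rate=1.0,
            peak_rate=2.5,
            resting_temp_ratio=2.19 ** 0.4,
            peak_temp_ratio=2.53 ** 0.4,
        ),
    )
    return StudyDesign(stages=stages)


def zero_effect_design() -> StudyDesign:
    """Same layout but identical truth in every stage x temperature cell."""
    base = default_study_design()
    flat = tuple(
        StageDesign(
            name=st.name,
            speeds_bl_s=st.speeds_bl_s,
            body_length_mm=st.body_length_mm,
            tbf_base_hz=12.0,
            tbf_speed_slope=0.0,
            tbf_temp_factor=1.0,
            wavelength_bl=0.8,
            head_amp_bl=0.03,
            tail_amp_bl=0.08,
            mean_sep_bl=2.0,
            sep_temp_factor=1.0,
            switch_rate_per_s=0.15,
            resting_rate=1.0,
            peak_rate=2.5,
            resting_temp_ratio=1.0,
            peak_temp_ratio=1.0,
        )
        for st in base.stages
    )
    return StudyDesign(stages=flat)


@dataclass
class StudyBundle:
    """In-memory synthetic study: raw data plus metadata and truth manifest."""

    metadata: pd.DataFrame
    midlines: dict[tuple[str, float], dict[str, MidlineSequence]]
    trajectories: dict[tuple[str, float], ShoalTrajectory]
    oxygen: dict[str, OxygenTrace]
    truth: dict[str, Any]


def _child_seed(base: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=base, spawn_key=tuple(key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def generate_study(
    design: StudyDesign, seed: int = 0, outdir=None
) -> StudyBundle:
    """Generate a full synthetic study under the given design.

    Per shoal: one oxygen trace; per (shoal, flow speed): one shoal
    trajectory and one midline sequence per fish.  Between-shoal variation
    is multiplicative Gaussian with coefficient ``shoal_cv``; within-shoal
    TBF varies across fish with SD ``fish_tbf_sd_hz``.  Deterministic given
    (design, seed).  When ``outdir`` is given, delimited raw-data files and
    a truth manifest are also written there.
    """
    meta_rows = []
    midlines: dict[tuple[str, float], dict[str, MidlineSequence]] = {}
    trajectories: dict[tuple[str, float], ShoalTrajectory] = {}
    oxygen: dict[str, OxygenTrace] = {}
    truth: dict[str, Any] = {"design": _design_to_dict(design), "seed": seed, "shoals": {}}
    seen_ids: set[str] = set()
    missing = set(design.missing_shoals)

    for si, st in enumerate(design.stages):
        prefix = STAGE_PREFIX.get(st.name, st.name[:1].upper())
        for num in range(1, design.shoals_per_stage + 1):
            if (st.name, num) in missing:
                continue
            shoal_id = f"{prefix}{num}"
            if shoal_id in seen_ids:
                raise ParameterError(f"duplicate shoal ID {shoal_id!r}")
            seen_ids.add(shoal_id)
            high = num % 2 == 1
            temp = design.temp_high_c if high else design.temp_low_c
            rng = np.random.default_rng(_child_seed(seed, si, num, 0))
            mult = lambda: float(1.0 + design.shoal_cv * rng.standard_normal())
            tbf_shoal = st.tbf_base_hz * (st.tbf_temp_factor if high else 1.0) * mult()
            sep_shoal = st.mean_sep_bl * (st.sep_temp_factor if high else 1.0) * mult()
            switch_shoal = max(st.switch_rate_per_s * mult(), 0.0)
            rest_rate = st.resting_rate * (st.resting_temp_ratio if high else 1.0) * mult()
            peak_rate = st.peak_rate * (st.peak_temp_ratio if high else 1.0) * mult()
            peak_rate = max(peak_rate, rest_rate)
            rec_temp = temp + 0.1 * float(rng.standard_normal())
            rec_sd = abs(design.temp_record_sd_c * (1.0 + 0.3 * float(rng.standard_normal())))

            shoal_truth: dict[str, Any] = {
                "stage": st.name,
                "treatment_temp_c": temp,
                "tbf_shoal_hz": tbf_shoal,
                "mean_sep_bl": sep_shoal,
                "switch_rate_per_s": switch_shoal,
                "resting_slope": rest_rate,
                "peak_slope": peak_rate,
                "per_speed": {},
            }

            # oxygen trace (one per shoal)
            rp = RespoSimParams(
                resting_slope=rest_rate,
                peak_slope=peak_rate,
                recovery_decay_min=design.recovery_decay_min,
                o2_start=design.o2_start,
                rest_duration_min=design.rest_duration_min,
                recovery_duration_min=design.recovery_duration_min,
                noise_sd=design.o2_noise_sd,
                temperature_c=temp,
                seed=_child_seed(seed, si, num, 1),
            )
            trace, _ = generate_oxygen_trace(rp, shoal_id=shoal_id, stage=st.name)
            oxygen[shoal_id] = trace

            for vi, speed in enumerate(st.speeds_bl_s):
                sp = ShoalSimParams(
                    n_fish=design.n_fish,
                    mean_sep_bl=sep_shoal,
                    switch_rate_per_s=switch_shoal,
                    flow_speed_bl_s=speed,
                    duration_s=design.traj_duration_s,
                    sample_hz=design.traj_sample_hz,
                    jitter_sd_bl=design.traj_jitter_sd_bl,
                    body_length_mm=st.body_length_mm,
                    seed=_child_seed(seed, si, num, 2, vi),
                )
                traj, traj_truth = generate_shoal_trajectory(sp)
                trajectories[(shoal_id, speed)] = traj

                fish_seqs: dict[str, MidlineSequence] = {}
                tbf_speed = tbf_shoal + st.tbf_speed_slope * (speed - 1.5)
                fish_rng = np.random.default_rng(_child_seed(seed, si, num, 3, vi))
                tbf_fish_vals = []
                for fi in range(design.n_fish):
                    tbf_fish = max(
                        tbf_speed + design.fish_tbf_sd_hz * float(fish_rng.standard_normal()),
                        0.5,
                    )
                    tbf_fish_vals.append(tbf_fish)
                    wp = WaveModelParams(
                        tbf_hz=tbf_fish,
                        wavelength_bl=st.wavelength_bl,
                        head_amp_bl=st.head_amp_bl,
                        tail_amp_bl=st.tail_amp_bl,
                        body_length_mm=st.body_length_mm,
                        frame_rate=design.frame_rate,
                        noise_sd_bl=design.midline_noise_sd_bl,
                        phase0=float(fish_rng.uniform(0.0, 2.0 * np.pi)),
                        seed=_child_seed(seed, si, num, 4, vi, fi),
                    )
                    fid = f"f{fi + 1}"
                    seq, _ = generate_midline_sequence(
                        wp, n_cycles=design.n_cycles, fish_id=fid
                    )
                    fish_seqs[fid] = seq
                midlines[(shoal_id, speed)] = fish_seqs
                shoal_truth["per_speed"][str(speed)] = {
                    "tbf_mean_hz": float(np.mean(tbf_fish_vals)),
                    "wavelength_bl": st.wavelength_bl,
                    "wave_speed_bl_s": float(np.mean(tbf_fish_vals)) * st.wavelength_bl,
                    "realized_switches": traj_truth.derived["realized_switches"],
                }

            truth["shoals"][shoal_id] = shoal_truth
            meta_rows.append(
                {
                    "shoal_id": shoal_id,
                    "stage": st.name,
                    "treatment_temp_c": temp,
                    "recorded_temp_c": f"{rec_temp:.1f} ± {rec_sd:.1f}",
                    "n_fish": design.n_fish,
                    "body_length_mm": st.body_length_mm,
                    "mass_g": round(0.35 - 0.01 * (temp - 28.0), 3)
                    if st.name == "adult"
                    else np.nan,
                    "speeds_bl_s": ";".join(str(v) for v in st.speeds_bl_s),
                }
            )

    bundle = StudyBundle(
        metadata=pd.DataFrame(meta_rows),
        midlines=midlines,
        trajectories=trajectories,
        oxygen=oxygen,
        truth=truth,
    )
    if outdir is not None:
        from . import io as skio

        skio.write_study_bundle(bundle, outdir)
    return bundle


def _design_to_dict(design: StudyDesign) -> dict[str, Any]:
    d = asdict(design)
    d["stages"] = [asdict(st) for st in design.stages]
    return d
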