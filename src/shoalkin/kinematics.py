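"""Midline swimming kinematics for undulatory swimmers.

Operates on digitized body midlines (ordered head-to-tail point sets, one per
video frame) and extracts the standard descriptors of body-caudal-fin
locomotion: tail-beat frequency (TBF), head and tail lateral amplitudes,
local and maximum body curvature, and the speed and wavelength of the
rearward-travelling bending wave.  All distances can be normalized by body
length (BL) so that fish of different sizes are directly comparable.

Conventions
-----------
* A midline is an ordered polyline of ``n_points`` (typically 200) points,
  index 0 at the snout, last index at the tail tip, equally spaced along the
  body.
* The flow / swimming axis is x; lateral excursion is y.
* Curvature is the inverse of the circumradius of the circle through three
  body points (kappa = 1/r); reported per BL by multiplying the per-mm value
  by the body length in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MidlineSequence",
    "CycleSpan",
    "KinematicsRecord",
    "NoCycleError",
    "InvalidInputError",
    "detect_beat_cycles",
    "tail_beat_frequency",
    "oscillation_amplitudes",
    "local_curvature",
    "max_body_curvature",
    "wave_speed_and_wavelength",
    "analyze_sequence",
    "summarize_shoal",
]

#: index half-window used for the three-point curvature stencil, as a body
#: fraction: the flanking points sit 5% BL away from the central one.
CURVATURE_SPACING_BL = 0.05


class NoCycleError(RuntimeError):
    """No complete tail-beat cycle could be delimited in the sequence."""


class InvalidInputError(ValueError):
    """Geometrically invalid input (e.g. coincident points)."""


@dataclass
class MidlineSequence:
    """Time-ordered midlines for a single fish.

    Parameters
    ----------
    fish_id : str
        Identifier of the fish.
    times : ndarray, shape (n_frames,)
        Frame times in seconds, strictly increasing.
    coords : ndarray, shape (n_frames, n_points, 2)
        Midline coordinates in mm, point index running head -> tail.
    body_length_mm : float
        Snout-to-tail body length.
    frame_rate : float
        Acquisition rate in frames per second.
    """

    fish_id: str
    times: np.ndarray
    coords: np.ndarray
    body_length_mm: float
    frame_rate: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise InvalidInputError("coords must have shape (n_frames, n_points, 2)")
        if self.coords.shape[0] != self.times.shape[0]:
            raise InvalidInputError("times and coords disagree on frame count")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise InvalidInputError("frame times must be strictly increasing")
        if not self.body_length_mm > 0:
            raise InvalidInputError("body_length_mm must be positive")
        if not self.frame_rate > 0:
            raise InvalidInputError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_points(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class CycleSpan:
    """One complete tail-beat cycle.

    ``start``/``stop`` are inclusive frame indices delimiting the cycle;
    ``t_start``/``t_end`` are sub-frame interpolated zero-crossing times of
    the tail-tip lateral signal, from which the cycle period is measured.
    """

    start: int
    stop: int
    t_start: float
    t_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class KinematicsRecord:
    """Per-fish (or per-shoal) kinematic summary; missing values are NaN."""

    tbf_hz: float = np.nan
    head_amp_bl: float = np.nan
    tail_amp_bl: float = np.nan
    head_tail_ratio: float = np.nan
    wave_speed_bl_s: float = np.nan
    wavelength_bl: float = np.nan
    max_curvature_per_bl: float = np.nan
    n_cycles_used: int = 0

    FIELDS = (
        "tbf_hz",
        "head_amp_bl",
        "tail_amp_bl",
        "head_tail_ratio",
        "wave_speed_bl_s",
        "wavelength_bl",
        "max_curvature_per_bl",
    )

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in self.FIELDS}
        d["n_cycles_used"] = self.n_cycles_used
        return d


# ---------------------------------------------------------------------------
# signals and cycle detection
# ---------------------------------------------------------------------------

def _end_signal(seq: MidlineSequence, head: bool) -> np.ndarray:
    """Lateral (y) signal averaged over the five head- or tail-most points."""
    pts = seq.coords[:, :5, 1] if head else seq.coords[:, -5:, 1]
    return pts.mean(axis=1)


def detect_beat_cycles(seq: MidlineSequence, min_run: int = 3) -> list[CycleSpan]:
    """Delimit complete tail-beat cycles from tail-tip zero crossings.

    The mean-subtracted tail-tip lateral signal (average of the last five
    midline points) changes sign twice per beat; every second sign change
    therefore delimits one full cycle.  Sign runs shorter than ``min_run``
    samples are ignored (hysteresis against noise-driven chatter near zero).

    Raises
    ------
    NoCycleError
        If fewer than three qualifying zero crossings exist (no full cycle).
    """
    y = _end_signal(seq, head=False)
    y = y - y.mean()
    sign = np.sign(y)
    # collapse zeros onto the previous sign so exact zeros do not split runs
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    if sign[0] == 0:
        nz = np.nonzero(sign)[0]
        if nz.size == 0:
            raise NoCycleError("tail-tip signal is flat: no cycle detected")
        sign[: nz[0]] = sign[nz[0]]

    # candidate crossings with run-length hysteresis
    crossings: list[float] = []  # fractional frame indices
    run_start = 0
    runs: list[tuple[int, int, float]] = []  # (start, stop_exclusive, sign)
    for i in range(1, sign.size + 1):
        if i == sign.size or sign[i] != sign[run_start]:
            runs.append((run_start, i, sign[run_start]))
            run_start = i
    # merge runs shorter than min_run into their predecessor
    merged: list[tuple[int, int, float]] = []
    for r in runs:
        if merged and (r[1] - r[0] < min_run or merged[-1][2] == r[2]):
            merged[-1] = (merged[-1][0], r[1], merged[-1][2])
        else:
            merged.append(r)
    for prev, nxt in zip(merged[:-1], merged[1:]):
        i = nxt[0]  # first frame of the new sign
        y0, y1 = y[i - 1], y[i]
        frac = 0.5 if y1 == y0 else y0 / (y0 - y1)
        crossings.append((i - 1) + frac)

    # boundary crossings: a record covering whole cycles starts/ends on a
    # crossing, which the sign-change scan cannot see.  Recover them when the
    # boundary sample is an exact zero, or when extrapolating one median
    # half-period beyond the outermost crossing lands (within a frame) on
    # the record boundary.
    scale = float(np.max(np.abs(y)))
    if scale > 0:
        if abs(y[0]) <= 1e-9 * scale and (not crossings or crossings[0] > 0.5):
            crossings.insert(0, 0.0)
        last = sign.size - 1
        if abs(y[last]) <= 1e-9 * scale and (not crossings or crossings[-1] < last - 0.5):
            crossings.append(float(last))
    if len(crossings) >= 2:
        half = float(np.median(np.diff(crossings)))
        # extrapolate one full period from the same-parity crossing (up- and
        # down-crossings shift oppositely under any DC offset, so same-parity
        # spacing is the clean period estimate); the 5-point tail mean carries
        # a spatial phase offset, so a record spanning whole oscillation
        # periods misses its boundary crossings by up to that offset — allow
        # a modest fraction of a period beyond the record
        arr = np.asarray(crossings)
        if arr.size >= 3:
            period = float(np.median(arr[2:] - arr[:-2]))
        else:
            period = 2.0 * half
        tol = max(1.0, 0.16 * half)  # frames
        if len(crossings) >= 2:
            p = crossings[1] - period
            if -tol <= p < crossings[0] - 0.5 * half:
                crossings.insert(0, p)
            last = sign.size - 1
            p = crossings[-2] + period
            if crossings[-1] + 0.5 * half < p <= last + tol:
                crossings.append(p)

    if len(crossings) < 3:
        raise NoCycleError("fewer than two zero crossings: no cycle detected")

    dt = np.diff(seq.times).mean()
    t0 = seq.times[0]
    cycles = []
    for k in range(0, len(crossings) - 2, 2):
        c0, c1 = crossings[k], crossings[k + 2]
        cycles.append(
            CycleSpan(
                start=max(0, int(np.ceil(c0))),
                stop=min(sign.size - 1, int(np.floor(c1))),
                t_start=t0 + c0 * dt,
                t_end=t0 + c1 * dt,
            )
        )
    return cycles


def tail_beat_frequency(seq: MidlineSequence, cycles: Sequence[CycleSpan]) -> float:
    """TBF in Hz: frame rate divided by the (fractional) frames per cycle.

    Equivalently the reciprocal of the interpolated cycle period; multi-cycle
    sequences return the per-cycle mean.
    """
    if not cycles:
        raise NoCycleError("no cycle provided")
    return float(np.mean([1.0 / c.duration for c in cycles]))


# ---------------------------------------------------------------------------
# amplitudes
# ---------------------------------------------------------------------------

def _harmonic_amplitude(t: np.ndarray, y: np.ndarray, period: float,
                        n_harmonics: int = 3) -> float:
    """Peak deviation from the mean of a harmonic fit at the beat period.

    A truncated Fourier series at the tail-beat fundamental is regressed on
    the signal; the amplitude is the maximum |fit - mean| of the fitted
    waveform evaluated densely over one period.  For a noiseless sinusoid
    this equals the true amplitude; under measurement noise it avoids the
    upward bias of a raw max-over-samples.
    """
    k_max = max(1, min(n_harmonics, (t.size - 1) // 4))
    w = 2.0 * np.pi / period
    cols = [np.ones_like(t)]
    for k in range(1, k_max + 1):
        cols.append(np.cos(k * w * t))
        cols.append(np.sin(k * w * t))
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    tt = np.linspace(0.0, period, 720, endpoint=False)
    fit = np.full_like(tt, beta[0])
    for k in range(1, k_max + 1):
        fit = fit + beta[2 * k - 1] * np.cos(k * w * tt) + beta[2 * k] * np.sin(k * w * tt)
    return float(np.max(np.abs(fit - beta[0])))


def oscillation_amplitudes(
    seq: MidlineSequence, cycles: Sequence[CycleSpan]
) -> tuple[float, float, float]:
    """Head and tail lateral amplitudes (BL) and their head/tail ratio.

    The head (tail) signal is the mean lateral position of the first (last)
    five midline points.  Amplitude is the maximum lateral oscillation about
    the time-mean path over a cycle — half the peak-to-peak excursion for a
    sinusoid — in BL.  Returns NaN for the ratio (with a warning) when the
    tail amplitude is zero.
    """
    if not cycles:
        raise NoCycleError("no cycle provided")
    head = _end_signal(seq, head=True)
    tail = _end_signal(seq, head=False)
    h_amps, t_amps = [], []
    for c in cycles:
        sl = slice(c.start, c.stop + 1)
        t = seq.times[sl] - seq.times[c.start]
        if np.ptp(head[sl]) == 0.0:
            h_amps.append(0.0)
        else:
            h_amps.append(_harmonic_amplitude(t, head[sl], c.duration))
        if np.ptp(tail[sl]) == 0.0:
            t_amps.append(0.0)
        else:
            t_amps.append(_harmonic_amplitude(t, tail[sl], c.duration))
    head_amp = float(np.mean(h_amps)) / seq.body_length_mm
    tail_amp = float(np.mean(t_amps)) / seq.body_length_mm
    if tail_amp == 0.0:
        warnings.warn("tail amplitude is zero; head:tail ratio undefined")
        return head_amp, tail_amp, np.nan
    return head_amp, tail_amp, head_amp / tail_amp


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------

def local_curvature(p1, p2, p3) -> float:
    """Curvature (1/mm) of the circle through three points: kappa = 1/r.

    The circumradius follows r = abc / (4 * area); collinear points have zero
    curvature, coincident points are invalid.  Multiply by the body length in
    mm to convert to per-BL units.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    a = np.linalg.norm(p2 - p3)
    b = np.linalg.norm(p1 - p3)
    c = np.linalg.norm(p1 - p2)
    if a == 0.0 or b == 0.0 or c == 0.0:
        raise InvalidInputError("coincident points have no defined curvature")
    cross = (p2[0] - p1[0]) * (p3[1] - p1[1]) - (p2[1] - p1[1]) * (p3[0] - p1[0])
    area = 0.5 * abs(cross)
    return 4.0 * area / (a * b * c)


def _curvature_step(n_points: int) -> int:
    """Index step realizing the 5% BL stencil spacing on an equally spaced
    midline (nearest-point selection, ties toward the head)."""
    return max(1, int(np.floor(CURVATURE_SPACING_BL * (n_points - 1) + 0.5)))


def _signed_curvature_profiles(coords: np.ndarray, step: int) -> np.ndarray:
    """Signed three-point curvature (1/mm) at every interior station.

    Parameters
    ----------
    coords : ndarray (n_frames, n_points, 2)
    step : stencil half-width in points.

    Returns
    -------
    ndarray (n_frames, n_points - 2*step); sign from the orientation of the
    point triple (positive = bending toward +y).
    """
    p1 = coords[:, : -2 * step, :]
    p2 = coords[:, step:-step, :]
    p3 = coords[:, 2 * step :, :]
    a = np.linalg.norm(p2 - p3, axis=2)
    b = np.linalg.norm(p1 - p3, axis=2)
    c = np.linalg.norm(p1 - p2, axis=2)
    cross = (p2[..., 0] - p1[..., 0]) * (p3[..., 1] - p1[..., 1]) - (
        p2[..., 1] - p1[..., 1]
    ) * (p3[..., 0] - p1[..., 0])
    denom = a * b * c
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0, 2.0 * cross / np.where(denom > 0, denom, 1.0), 0.0)
    return kappa


def _cycle_frames(seq: MidlineSequence, cycles: Sequence[CycleSpan]) -> np.ndarray:
    idx: list[int] = []
    for c in cycles:
        idx.extend(range(c.start, c.stop + 1))
    return np.unique(np.asarray(idx, dtype=int))


def max_body_curvature(seq: MidlineSequence, cycles: Sequence[CycleSpan]) -> float:
    """Maximum body curvature over the cycle, in 1/BL.

    Iterates a three-point stencil spanning 5% BL on either side of every
    interior midline station, in every frame of the given cycles, and returns
    the largest curvature magnitude scaled to per-BL units.
    """
    if not cycles:
        raise NoCycleError("no cycle provided")
    step = _curvature_step(seq.n_points)
    if seq.n_points < 2 * step + 1:
        raise InvalidInputError("midline too short for the 5% BL stencil")
    frames = _cycle_frames(seq, cycles)
    kappa = _signed_curvature_profiles(seq.coords[frames], step)
    return float(np.max(np.abs(kappa))) * seq.body_length_mm


# ---------------------------------------------------------------------------
# wave speed and wavelength
# ---------------------------------------------------------------------------

def _arc_fractions(coords: np.ndarray) -> np.ndarray:
    """Per-frame normalized arc-length coordinate of every midline point."""
    seg = np.linalg.norm(np.diff(coords, axis=1), axis=2)
    cum = np.concatenate([np.zeros((coords.shape[0], 1)), np.cumsum(seg, axis=1)], axis=1)
    return cum / cum[:, -1:]


def wave_speed_and_wavelength(
    seq: MidlineSequence,
    cycles: Sequence[CycleSpan],
    tbf_hz: float,
    posterior_from_bl: float = 0.5,
    min_tracked_frames: int = 4,
    smooth_stations: int = 11,
    min_curvature_per_bl: float = 0.1,
    coord_smooth_window: int = 31,
) -> tuple[float, float]:
    """Body-wave speed (BL/s) and wavelength (BL) from curvature crest travel.

    For every frame the arc-length positions of the curvature crests in the
    posterior half of the body are located; as the bending wave travels
    tailward each crest advances at the wave speed.  Concretely:

    1. midline coordinates are smoothed along the body with a zero-phase
       Savitzky-Golay filter (symmetric and linear, so crest positions are
       unbiased) and signed three-point curvature profiles are computed at
       every interior station;
    2. each posterior station's curvature time series is projected onto the
       fundamental harmonic at the beat frequency (exact for a noiseless
       travelling wave; averages positional jitter over all frames), giving
       an oscillation amplitude and phase per station;
    3. the unwrapped station phase profile, lightly smoothed along the body,
       is inverted per frame: a curvature crest sits wherever the local
       phase satisfies ``2*pi*f*t + phase(s) = pi/2 (mod pi)``, so each
       admissible crest index maps to an arc-length position by monotone
       interpolation of the phase profile;
    4. crest positions are grouped by crest index (a crest exiting at the
       tail re-enters anteriorly as the next index) and a common
       least-squares slope of position (BL) vs time (s) across the groups
       gives the wave speed; wavelength = speed / TBF.

    Returns ``(nan, nan)`` with a warning when no crest can be tracked (e.g.
    a rigidly translating straight body, or a non-travelling phase profile)
    or fewer than ``min_tracked_frames`` crest observations remain.
    """
    if not cycles:
        raise NoCycleError("no cycle provided")
    if not np.isfinite(tbf_hz) or tbf_hz <= 0:
        raise InvalidInputError("tbf_hz must be positive")
    from scipy.ndimage import uniform_filter1d
    from scipy.signal import savgol_filter

    step = _curvature_step(seq.n_points)
    frames = _cycle_frames(seq, cycles)
    coords = seq.coords[frames]
    times = seq.times[frames]
    window = min(coord_smooth_window, seq.n_points - 1)
    if window % 2 == 0:
        window -= 1
    if window >= 5:
        coords = savgol_filter(coords, window, polyorder=3, axis=1, mode="interp")
    kappa = _signed_curvature_profiles(coords, step)  # (F, S)

    # fundamental-harmonic fit per station: kappa ~ a sin(wt) + b cos(wt)
    omega = 2.0 * np.pi * tbf_hz
    tt = times - times[0]
    design = np.column_stack([np.sin(omega * tt), np.cos(omega * tt), np.ones_like(tt)])
    coef, *_ = np.linalg.lstsq(design, kappa, rcond=None)
    a, b = coef[0], coef[1]
    amp = np.hypot(a, b)
    if amp.max() * seq.body_length_mm < min_curvature_per_bl:
        warnings.warn("no curvature crest to track (body nearly straight)")
        return np.nan, np.nan

    # station arc positions (use frame 0; equal spacing makes them constant)
    s_all = _arc_fractions(coords)[0]
    s_stations = s_all[step : seq.n_points - step]
    post = s_stations >= posterior_from_bl
    if post.sum() < 5:
        warnings.warn("posterior body segment too short to track the wave")
        return np.nan, np.nan
    s_post = s_stations[post]
    amp = amp[post]

    # unwrapped phase profile; tailward travel means phase decreases with s
    psi = np.unwrap(np.arctan2(b[post], a[post]))
    if smooth_stations > 1 and psi.size > smooth_stations:
        psi = uniform_filter1d(psi, smooth_stations, mode="nearest")
    span = psi[0] - psi[-1]
    if abs(span) < 0.1:
        warnings.warn("phase profile is flat: no travelling wave to track")
        return np.nan, np.nan
    if span < 0:  # headward convention: flip so the profile decreases
        psi = -psi
        omega_signed = -omega
    else:
        omega_signed = omega
    # enforce monotone decrease so the profile can be inverted
    psi = np.minimum.accumulate(psi)

    # per frame, solve psi(s) = pi/2 + k*pi - omega*t for each crest index k
    lo, hi = psi[-1], psi[0]
    ts_pts: list[float] = []
    ss_pts: list[float] = []
    ks_pts: list[int] = []
    x_incr = -psi  # increasing in s, for np.interp
    for fi, t in enumerate(tt):
        base = 0.5 * np.pi - omega_signed * float(t)
        k_lo = int(np.ceil((lo - base) / np.pi))
        k_hi = int(np.floor((hi - base) / np.pi))
        for k in range(k_lo, k_hi + 1):
            target = base + k * np.pi
            s_pos = float(np.interp(-target, x_incr, s_post))
            ts_pts.append(float(times[fi]))
            ss_pts.append(s_pos)
            ks_pts.append(k)

    if len(ts_pts) < min_tracked_frames:
        warnings.warn("fewer than %d trackable crest frames" % min_tracked_frames)
        return np.nan, np.nan

    # common least-squares slope across crest-index groups
    ts_arr = np.asarray(ts_pts)
    ss_arr = np.asarray(ss_pts)
    ks_arr = np.asarray(ks_pts)
    sxy = sxx = 0.0
    for k in np.unique(ks_arr):
        m = ks_arr == k
        if m.sum() < 2:
            continue
        tc = ts_arr[m] - ts_arr[m].mean()
        sxy += float(np.dot(tc, ss_arr[m] - ss_arr[m].mean()))
        sxx += float(np.dot(tc, tc))
    if sxx == 0.0:
        warnings.warn("fewer than %d trackable crest frames" % min_tracked_frames)
        return np.nan, np.nan
    speed = abs(sxy / sxx)  # BL/s
    return float(speed), float(speed / tbf_hz)


# ---------------------------------------------------------------------------
# per-sequence and per-shoal summaries
# ---------------------------------------------------------------------------

def analyze_sequence(seq: MidlineSequence) -> KinematicsRecord | None:
    """Full kinematic record for one sequence; None when no cycle is found.

    Fish contributing less than one full tail-beat cycle yield no kinematics.
    """
    try:
        cycles = detect_beat_cycles(seq)
    except NoCycleError:
        return None
    tbf = tail_beat_frequency(seq, cycles)
    head_amp, tail_amp, ratio = oscillation_amplitudes(seq, cycles)
    max_curv = max_body_curvature(seq, cycles)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        speed, wavelength = wave_speed_and_wavelength(seq, cycles, tbf)
    return KinematicsRecord(
        tbf_hz=tbf,
        head_amp_bl=head_amp,
        tail_amp_bl=tail_amp,
        head_tail_ratio=ratio,
        wave_speed_bl_s=speed,
        wavelength_bl=wavelength,
        max_curvature_per_bl=max_curv,
        n_cycles_used=len(cycles),
    )


def summarize_shoal(
    per_fish: Mapping[str, Sequence[KinematicsRecord]],
) -> tuple[KinematicsRecord, dict[str, int]]:
    """Average kinematics to one record per shoal.

    Each fish's records (one per independent video sequence, typically 1-2)
    are averaged first; the shoal record is then the unweighted mean across
    fish.  Missing (NaN) fields are excluded pairwise, and the returned
    counts report how many fish contributed to each field.
    """
    if not per_fish:
        raise ValueError("summarize_shoal requires at least one fish record")
    fish_values: dict[str, list[float]] = {name: [] for name in KinematicsRecord.FIELDS}
    n_cycles_total = 0
    for fish_id, records in per_fish.items():
        if not records:
            continue
        for name in KinematicsRecord.FIELDS:
            vals = np.asarray([getattr(r, name) for r in records], dtype=float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fish_values[name].append(float(np.nanmean(vals)))
        n_cycles_total += sum(r.n_cycles_used for r in records)
    if all(len(v) == 0 for v in fish_values.values()):
        raise ValueError("summarize_shoal received only empty record lists")
    out = KinematicsRecord(n_cycles_used=n_cycles_total)
    counts: dict[str, int] = {}
    for name, vals in fish_values.items():
        arr = np.asarray(vals, dtype=float)
        finite = np.isfinite(arr)
        counts[name] = int(finite.sum())
        setattr(out, name, float(arr[finite].mean()) if finite.any() else np.nan)
    return out, counts
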