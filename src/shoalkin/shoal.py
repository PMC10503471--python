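"""Shoal cohesion metrics: mean separation distance and position-switch rate.

A shoal trajectory holds one reference point per fish per frame (in a flow
tank the flow axis defines the ecologically meaningful streamwise order).
Two group-level descriptors are computed:

* mean separation distance — the mean inter-individual Euclidean distance,
  normalized by the shoal-mean body length (BL); a cohesion measure;
* position-switch rate — how often two shoal members exchange streamwise
  order (events per second); a measure of formation volatility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = ["ShoalTrajectory", "mean_separation_distance", "position_switch_rate"]


@dataclass
class ShoalTrajectory:
    """Per-frame reference positions of the shoal members.

    Parameters
    ----------
    times : ndarray (n_frames,)
        Sample times in seconds, strictly increasing.
    positions : ndarray (n_frames, n_fish, 2)
        Reference position of each fish in mm (body centroid of the digitized
        midline, or the provided trajectory point).
    body_lengths_mm : ndarray (n_fish,)
        Individual body lengths; BL normalization uses their mean.
    flow_axis : ndarray (2,)
        Unit vector of the flow direction (streamwise order is taken along
        this axis). Defaults to +x.
    """

    times: np.ndarray
    positions: np.ndarray
    body_lengths_mm: np.ndarray
    flow_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.body_lengths_mm = np.asarray(self.body_lengths_mm, dtype=float)
        self.flow_axis = np.asarray(self.flow_axis, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (n_frames, n_fish, 2)")
        if self.positions.shape[0] != self.times.shape[0]:
            raise ValueError("times and positions disagree on frame count")
        if self.positions.shape[1] != self.body_lengths_mm.shape[0]:
            raise ValueError("body_lengths_mm must have one entry per fish")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(self.body_lengths_mm > 0):
            raise ValueError("body lengths must be positive")
        norm = np.linalg.norm(self.flow_axis)
        if norm == 0:
            raise ValueError("flow_axis must be a nonzero vector")
        self.flow_axis = self.flow_axis / norm

    @property
    def n_fish(self) -> int:
        return self.positions.shape[1]

    @property
    def mean_body_length_mm(self) -> float:
        return float(self.body_lengths_mm.mean())


def mean_separation_distance(traj: ShoalTrajectory) -> float:
    """Mean inter-individual distance in BL.

    Per frame, each fish's separation is its mean Euclidean distance to the
    other n-1 fish; fish are averaged, then frames, and the result is
    normalized by the shoal-mean body length.  Because every pair enters two
    per-fish means symmetrically this equals the unordered-pairs mean.
    """
    if traj.n_fish < 2:
        raise ValueError("mean separation distance requires at least two fish")
    if traj.times.size < 1:
        raise ValueError("trajectory has no frames")
    diff = traj.positions[:, :, None, :] - traj.positions[:, None, :, :]
    dist = np.linalg.norm(diff, axis=3)  # (F, N, N)
    n = traj.n_fish
    per_fish = dist.sum(axis=2) / (n - 1)  # diagonal contributes 0
    return float(per_fish.mean()) / traj.mean_body_length_mm


def _pair_switch_count(d: np.ndarray, h: float) -> int:
    """Alternation count of the hysteresis-confirmed sign of a gap signal.

    ``d`` is the streamwise gap of one fish pair over time; the confirmed
    sign flips only once the gap crosses beyond the opposite hysteresis band
    (|d| > h), suppressing jitter-driven rank chatter.
    """
    conf = np.where(d > h, 1, np.where(d < -h, -1, 0))
    state = np.sign(d[0])
    if state == 0:
        nz = conf[conf != 0]
        if nz.size == 0:
            return 0
        state = nz[0]
    flips = 0
    for s in conf[conf != 0]:
        if s != state:
            flips += 1
            state = s
    return flips


def position_switch_rate(
    traj: ShoalTrajectory,
    sample_hz: float = 10.0,
    hysteresis_bl: float = 0.05,
) -> float:
    """Rate of streamwise position switches, in events per second.

    Positions are resampled at ``sample_hz`` (linear interpolation; raw
    video-rate trajectories are jitter-dominated for rank order), projected
    onto the flow axis, and every unordered fish pair contributes one event
    each time its streamwise order inverts.  An inversion is only confirmed
    once the pair's gap exceeds ``hysteresis_bl`` body lengths on the other
    side, so jitter below the band never registers.  Summed over pairs and
    divided by the record duration.  A full rank order change decomposes into
    its pairwise (Kendall-discordant) inversions, each counted once.
    """
    if traj.n_fish < 2:
        raise ValueError("position switches require at least two fish")
    duration = float(traj.times[-1] - traj.times[0])
    if duration <= 0:
        raise ValueError("trajectory duration must be positive")
    n_samples = int(np.floor(duration * sample_hz)) + 1
    if n_samples < 2:
        raise ValueError("duration too short: fewer than 2 resampled frames")
    t_new = traj.times[0] + np.arange(n_samples) / sample_hz
    x = np.empty((n_samples, traj.n_fish))
    proj = traj.positions @ traj.flow_axis
    for i in range(traj.n_fish):
        x[:, i] = np.interp(t_new, traj.times, proj[:, i])
    h = hysteresis_bl * traj.mean_body_length_mm
    total = 0
    for i, j in combinations(range(traj.n_fish), 2):
        total += _pair_switch_count(x[:, i] - x[:, j], h)
    return total / duration
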