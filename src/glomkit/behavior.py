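"""Open-arena odor-localization analysis: tracking and approach metrics.

An animal explores a circular arena; at odor onset one wall inlet becomes
odorized. Localization is scored as the first time after onset the animal
comes within ``arrival_radius`` (1 cm by default) of the active inlet.
Reported metrics: latency to arrival, path length travelled from onset to
arrival, distance from the source at onset, and mean speed before vs after
onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .datatypes import ArenaGeometry, Trajectory


@dataclass
class BehaviorMetrics:
    latency: float  # s from odor onset; NaN if never arrived
    path_length: float  # cm from onset to arrival (or to end)
    initial_distance: float  # cm from source at onset
    mean_velocity_pre: float  # cm/s
    mean_velocity_post: float  # cm/s
    arrived: bool
    excluded: bool = False
    exclusion_reason: str = ""


def track_centroid(
    frames: np.ndarray,
    pixel_scale: float,
    frame_rate: float = 8.0,
    intensity_threshold: float = 0.5,
    polarity: int = 1,
) -> Trajectory:
    """Centroid of the largest supra-threshold blob per frame, in cm.

    ``intensity_threshold`` is a fraction of each frame's intensity range;
    ``polarity`` -1 tracks a dark animal on a bright background. Frames with
    no blob are linearly interpolated from their neighbors.
    """
    frames = np.asarray(frames, dtype=float)
    if polarity < 0:
        frames = -frames
    n = frames.shape[0]
    xy = np.full((n, 2), np.nan)
    for i in range(n):
        f = frames[i]
        lo, hi = f.min(), f.max()
        if hi <= lo:
            continue
        mask = f > lo + intensity_threshold * (hi - lo)
        labels, n_comp = ndimage.label(mask)
        if n_comp == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_comp + 1))
        biggest = int(np.argmax(sizes)) + 1
        cy, cx = ndimage.center_of_mass(f, labels, biggest)
        xy[i] = (cx * pixel_scale, cy * pixel_scale)
    # interpolate frames where detection failed
    good = ~np.isnan(xy[:, 0])
    if not good.any():
        raise ValueError("no animal detected in any frame")
    idx = np.arange(n)
    for d in range(2):
        xy[:, d] = np.interp(idx, idx[good], xy[good, d])
    times = idx / frame_rate
    return Trajectory(times=times, positions=xy)


def localization_metrics(traj: Trajectory, arena: ArenaGeometry) -> BehaviorMetrics:
    """Latency, path length, initial distance and speeds for one trajectory.

    Arrival is the first sample at or after odor onset whose distance to the
    active inlet is <= arrival_radius. Path length sums segment lengths from
    onset to arrival (to trajectory end if the animal never arrives).
    """
    t = traj.times
    onset = arena.odor_onset
    if t[-1] < onset:
        raise ValueError("trajectory ends before odor onset")
    source = arena.active_inlet_position()
    dist = np.hypot(*(traj.positions - source).T)

    post = t >= onset
    i_on = int(np.argmax(post))
    initial_distance = float(dist[i_on])

    hits = np.flatnonzero(post & (dist <= arena.arrival_radius))
    arrived = hits.size > 0
    i_arr = int(hits[0]) if arrived else t.size - 1
    latency = float(t[i_arr] - onset) if arrived else float("nan")

    seg = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)
    path_length = float(seg[i_on:i_arr].sum())

    def mean_speed(i0: int, i1: int) -> float:
        if i1 <= i0:
            return float("nan")
        return float(seg[i0:i1].sum() / (t[i1] - t[i0]))

    return BehaviorMetrics(
        latency=latency,
        path_length=path_length,
        initial_distance=initial_distance,
        mean_velocity_pre=mean_speed(0, i_on),
        mean_velocity_post=mean_speed(i_on, i_arr),
        arrived=arrived,
    )


def apply_exclusion(
    metrics: BehaviorMetrics,
    rule: Optional[str] = "min_initial_distance",
    cutoff: float = 10.0,
) -> BehaviorMetrics:
    """Flag a trial for exclusion by the animal's starting distance.

    rule "min_initial_distance" excludes animals starting closer than
    ``cutoff`` cm to the source (too easy a trial); "max_initial_distance"
    excludes animals starting farther than ``cutoff``. Comparisons are
    strict, so a start exactly at the cutoff is kept. ``rule=None``
    disables exclusion.
    """
    if rule is None:
        return metrics
    if rule == "min_initial_distance":
        excluded = metrics.initial_distance < cutoff
        reason = f"initial distance {metrics.initial_distance:.2f} cm < {cutoff} cm"
    elif rule == "max_initial_distance":
        excluded = metrics.initial_distance > cutoff
        reason = f"initial distance {metrics.initial_distance:.2f} cm > {cutoff} cm"
    else:
        raise ValueError(f"unknown exclusion rule: {rule!r}")
    metrics.excluded = bool(excluded)
    metrics.exclusion_reason = reason if excluded else ""
    return metrics
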