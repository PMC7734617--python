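"""Per-trial navigation metrics.

Seven parameters are computed for each navigation trial:

* success / no success in finding the reward within the time limit,
* time to reward (s),
* the ordered list (and count) of visited alleys,
* total path length, TPL (m),
* trial duration (s) and mean speed (m/s),
* distance error, DE (%) = 100 · (travelled − ideal) / ideal,
* rotation angle, RA (deg) = participant's cumulative rotation − the
  ideal path's minimum rotation.

Capture convention.  The reward is invisible and triggers at a capture
radius, so a run that stops exactly at the capture boundary has travelled
``capture_radius`` metres less than the full ideal path.  To keep DE of a
perfect run at exactly 0 the path is truncated at the *interpolated*
capture crossing and completed with the straight stub from the crossing
point to the reward coordinate ("capture completion").  The travelled
distance of a perfect run then equals the ideal length, and DE ≥ 0 holds
for every successful run by minimality of the ideal polyline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .io import Trajectory
from .maze import IdealPath, Maze, TrialSpec, ideal_path

__all__ = [
    "TrialMetrics",
    "CaptureEvent",
    "MetricComputationError",
    "total_path_length",
    "detect_success",
    "visited_alleys",
    "distance_error",
    "rotation_angle",
    "compute_trial_metrics",
]


class MetricComputationError(ValueError):
    """A metric is undefined for this input (e.g. stationary trajectory)."""


@dataclass(frozen=True)
class CaptureEvent:
    """First crossing of a reward capture boundary, with interpolation."""

    alley: int
    time_s: float
    arc_length_m: float  # travelled distance at the crossing
    point: np.ndarray  # crossing coordinate
    sample_index: int  # index of the first sample at/after the crossing


@dataclass
class TrialMetrics:
    """The seven per-trial navigation parameters."""

    success: bool
    time_to_reward_s: Optional[float]
    reached_alley: Optional[int]
    visited_alleys: Tuple[int, ...]
    visited_n: int
    tpl_m: float
    duration_s: float
    mean_speed_m_s: Optional[float]
    de_pct: Optional[float]
    ra_deg: Optional[float]
    notes: Tuple[str, ...] = ()


def sample_ideal_trajectory(
    path: IdealPath, speed_m_s: float = 8.2, rate_hz: float = 120.0
) -> Trajectory:
    """Constant-speed sampling of an ideal polyline as a Trajectory.

    Sample positions are the uniform time grid *plus* the polyline corners
    (at their exact arc positions), so the piecewise-linear trajectory
    retraces the polyline exactly: its travelled distance equals the ideal
    length to machine precision.
    """
    pts = np.asarray(path.polyline, dtype=float)
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = float(arc[-1])
    grid = np.arange(0.0, total, speed_m_s / rate_hz)
    s = np.unique(np.concatenate([grid, arc]))
    x = np.interp(s, arc, pts[:, 0])
    y = np.interp(s, arc, pts[:, 1])
    return Trajectory(s / speed_m_s, x, y, rate_hz)


# ------------------------------------------------------------------ primitives


def total_path_length(traj: Trajectory) -> float:
    """Sum of Euclidean distances between consecutive samples (m)."""
    if len(traj) < 2:
        raise MetricComputationError("total path length needs at least two samples")
    d = np.diff(traj.xy, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _cumulative_arc(xy: np.ndarray) -> np.ndarray:
    d = np.diff(xy, axis=0)
    return np.concatenate([[0.0], np.cumsum(np.hypot(d[:, 0], d[:, 1]))])


def find_capture(traj: Trajectory, spec: TrialSpec, maze: Maze) -> Optional[CaptureEvent]:
    """First entry of the path into any reward capture disc, or None.

    The crossing is interpolated along the segment that enters the disc, so
    the capture time and travelled arc length are exact for piecewise-linear
    motion.  The time limit is *not* applied here (see
    :func:`detect_success`).
    """
    xy = traj.xy
    r = maze.config.reward_capture_radius
    best: Optional[CaptureEvent] = None
    for alley in sorted(spec.reward_alleys):
        c = maze.reward_point(alley)
        dist = np.hypot(xy[:, 0] - c[0], xy[:, 1] - c[1])
        inside = dist <= r
        if not inside.any():
            continue
        i = int(np.argmax(inside))
        if i == 0:
            ev = CaptureEvent(alley, float(traj.time_s[0]), 0.0, xy[0].copy(), 0)
        else:
            p0, p1 = xy[i - 1], xy[i]
            seg = p1 - p0
            a = float(seg @ seg)
            f0 = p0 - c
            b = 2.0 * float(f0 @ seg)
            cc = float(f0 @ f0) - r * r
            disc = max(b * b - 4 * a * cc, 0.0)
            s = (-b - math.sqrt(disc)) / (2 * a) if a > 0 else 0.0
            s = min(max(s, 0.0), 1.0)
            point = p0 + s * seg
            arc = _cumulative_arc(xy[: i + 1])
            arc_len = float(arc[i - 1] + s * math.sqrt(a))
            t = float(traj.time_s[i - 1] + s * (traj.time_s[i] - traj.time_s[i - 1]))
            ev = CaptureEvent(alley, t, arc_len, point, i)
        if best is None or ev.time_s < best.time_s:
            best = ev
    return best


def detect_success(
    traj: Trajectory, spec: TrialSpec, maze: Maze
) -> Tuple[bool, Optional[float], Optional[int]]:
    """(success, time_to_reward, reached_alley) under the trial time limit."""
    ev = find_capture(traj, spec, maze)
    t0 = float(traj.time_s[0])
    if ev is None or ev.time_s - t0 > spec.time_limit_s:
        return False, None, None
    return True, ev.time_s - t0, ev.alley


def _truncated_xy(traj: Trajectory, ev: Optional[CaptureEvent]) -> np.ndarray:
    """Path points up to (and including) the interpolated capture crossing."""
    if ev is None:
        return traj.xy
    return np.vstack([traj.xy[: ev.sample_index + 1][:-1], ev.point]) if ev.sample_index > 0 else traj.xy[:1]


def visited_alleys(
    traj: Trajectory,
    maze: Maze,
    depth_fraction: float = 0.10,
    start_alley: Optional[int] = None,
    capture: Optional[CaptureEvent] = None,
) -> Tuple[int, ...]:
    """Ordered unique alleys entered deeper than ``depth_fraction`` × length.

    The start alley is always counted first; samples after reward capture
    are ignored.  When ``start_alley`` is omitted it is inferred from the
    first sample's corridor (if any).
    """
    xy = traj.xy if capture is None else traj.xy[: max(capture.sample_index + 1, 1)]
    depth, inside = maze.alley_depths(xy)
    threshold = depth_fraction * maze.config.alley_length
    entered = inside & (depth > threshold)

    order: List[int] = []
    if start_alley is not None:
        order.append(int(start_alley))
    elif inside[0].any():
        order.append(int(np.argmax(inside[0])) + 1)
    first_idx = []
    for a in range(5):
        col = entered[:, a]
        if col.any():
            first_idx.append((int(np.argmax(col)), a + 1))
    for _, alley in sorted(first_idx):
        if alley not in order:
            order.append(alley)
    return tuple(order)


def _ideal_for_trial(
    spec: TrialSpec, maze: Maze, reached_alley: Optional[int]
) -> IdealPath:
    """Reference ideal path: to the reached reward on success, else the nearer reward."""
    if reached_alley is not None:
        return ideal_path(spec.start_alley, reached_alley, maze)
    paths = [ideal_path(spec.start_alley, a, maze) for a in sorted(spec.reward_alleys)]
    return min(paths, key=lambda p: p.length)


def _travelled(traj: Trajectory, ev: Optional[CaptureEvent], maze: Maze) -> float:
    """Travelled distance with capture completion (see module docstring)."""
    if ev is None:
        return total_path_length(traj)
    stub = float(np.hypot(*(maze.reward_point(ev.alley) - ev.point)))
    return ev.arc_length_m + stub


def distance_error(
    traj: Trajectory, spec: TrialSpec, maze: Maze, capture: Optional[CaptureEvent] = None
) -> float:
    """Distance error DE (%) = 100 · (travelled − ideal) / ideal.

    On success the travelled distance is truncated at capture and completed
    to the reward coordinate, and the ideal is the path to the reached
    reward; on failure the full travelled distance is compared against the
    nearer reward's ideal path.
    """
    if capture is None:
        capture = find_capture(traj, spec, maze)
    if capture is not None and capture.time_s - float(traj.time_s[0]) > spec.time_limit_s:
        capture = None
    ideal = _ideal_for_trial(spec, maze, capture.alley if capture else None)
    if ideal.length <= 0:
        raise MetricComputationError("degenerate ideal path of zero length")
    travelled = _travelled(traj, capture, maze)
    return 100.0 * (travelled - ideal.length) / ideal.length


def _decimate_by_arc(xy: np.ndarray, min_step: float) -> np.ndarray:
    """Sub-sample path points at ≥ ``min_step`` metres of travelled arc.

    Suppresses jitter-induced heading noise: headings are taken between
    points spaced at least ``min_step`` apart along the path.
    """
    arc = _cumulative_arc(xy)
    total = arc[-1]
    if total < min_step:
        return xy[:1]
    grid = np.arange(0.0, total, min_step)
    idx = np.unique(np.searchsorted(arc, grid, side="left"))
    if idx[-1] != len(xy) - 1:
        idx = np.append(idx, len(xy) - 1)
    return xy[idx]


def rotation_angle(
    traj: Trajectory,
    spec: TrialSpec,
    maze: Maze,
    min_step: float = 0.05,
    capture: Optional[CaptureEvent] = None,
) -> float:
    """Rotation angle RA (deg) = participant's rotations − minimum rotations.

    The participant's cumulative rotation is the summed absolute heading
    change over successive displacement vectors after decimating the path
    to steps of at least ``min_step`` metres, truncated at reward capture.
    The minimum rotation comes from the trial's ideal path.  RA may be
    slightly negative through discretisation; it is reported as computed.
    """
    if capture is None:
        capture = find_capture(traj, spec, maze)
    if capture is not None and capture.time_s - float(traj.time_s[0]) > spec.time_limit_s:
        capture = None
    xy = _truncated_xy(traj, capture)
    pts = _decimate_by_arc(xy, min_step)
    if len(pts) < 3:
        raise MetricComputationError(
            "stationary trajectory: fewer than three displacement steps of "
            f"at least {min_step} m"
        )
    d = np.diff(pts, axis=0)
    headings = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    dh = (np.diff(headings) + 180.0) % 360.0 - 180.0
    participant = float(np.abs(dh).sum())
    ideal = _ideal_for_trial(spec, maze, capture.alley if capture else None)
    return participant - ideal.min_rotation_deg


def compute_trial_metrics(
    traj: Trajectory,
    spec: TrialSpec,
    maze: Maze,
    depth_fraction: float = 0.10,
    min_step: float = 0.05,
    speed_mode: str = "path",
) -> TrialMetrics:
    """All seven per-trial parameters in one pass.

    ``speed_mode="path"`` defines mean speed as TPL / duration (duration =
    time of reward capture on success, else the full recorded duration);
    ``"instantaneous"`` averages per-sample speeds instead.
    """
    notes: List[str] = []
    success, t_reward, reached = detect_success(traj, spec, maze)
    capture = find_capture(traj, spec, maze) if success else None

    tpl = _travelled(traj, capture, maze) if success else total_path_length(traj)
    duration = t_reward if success else traj.duration_s
    visited = visited_alleys(
        traj, maze, depth_fraction=depth_fraction, start_alley=spec.start_alley, capture=capture
    )
    if speed_mode == "instantaneous":
        xy = _truncated_xy(traj, capture)
        tt = traj.time_s[: len(xy)]
        seg = np.hypot(*np.diff(xy, axis=0).T)
        dt = np.diff(tt[: len(xy)])
        good = dt > 0
        speed = float(np.mean(seg[good] / dt[good])) if good.any() else None
    else:
        # distance actually walked over time actually walked: on success the
        # capture-completion stub is excluded (no time is spent on it)
        walked = capture.arc_length_m if capture is not None else tpl
        speed = (walked / duration) if duration and duration > 0 else None

    try:
        de = distance_error(traj, spec, maze, capture=capture if success else None)
    except MetricComputationError as exc:
        de = None
        notes.append(f"de: {exc}")
    try:
        ra = rotation_angle(traj, spec, maze, min_step=min_step, capture=capture if success else None)
    except MetricComputationError as exc:
        ra = None
        notes.append(f"ra: {exc}")

    return TrialMetrics(
        success=success,
        time_to_reward_s=t_reward,
        reached_alley=reached,
        visited_alleys=visited,
        visited_n=len(visited),
        tpl_m=tpl,
        duration_s=float(duration) if duration is not None else traj.duration_s,
        mean_speed_m_s=speed,
        de_pct=de,
        ra_deg=ra,
        notes=tuple(notes),
    )
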