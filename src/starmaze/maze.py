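"""Parametric geometry of the pentagonal star maze and the canonical trial protocol.

The maze is a regular pentagon with five corridors ("alleys") radiating
outward from its vertices.  A hidden reward sits at the far end of one (or
two) alleys and is captured when the navigator comes within a fixed radius
of it.  Landmarks (houses, swings, ...) sit in the gaps between adjacent
alley ends and support allocentric (world-centred) navigation; stripping
them ("bare" maze) forces egocentric (body-centred) navigation.

Coordinate convention: planar metres, origin at the pentagon centroid,
alley 1 pointing along +y, alley *i* centred at heading 90° + (i−1)·72°
measured counter-clockwise from +x.  Trial indices are 1-based.

The published task geometry is known only through a single calibration
constraint: the ideal alley-1 → alley-3 path is 246 m long.  The default
configuration keeps a circumradius of 8 m and solves the alley length from
that constraint; every dimension is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from shapely.geometry import Point, Polygon

__all__ = [
    "N_ALLEYS",
    "IDEAL_1_TO_3_M",
    "MazeConfig",
    "Maze",
    "IdealPath",
    "TrialSpec",
    "build_maze",
    "locate",
    "ideal_path",
    "default_protocol",
    "default_alley_length",
]

N_ALLEYS = 5
#: Length (m) of the ideal alley-1 → alley-3 path, the single published
#: calibration constraint on the maze dimensions.
IDEAL_1_TO_3_M = 246.0

DEFAULT_LANDMARKS: Mapping[Tuple[int, int], str] = {
    (1, 2): "red_house",
    (2, 3): "swing",
    (3, 4): "blue_house",
    (4, 5): "slide",
    (5, 1): "round_house",
}


class MazeConfigError(ValueError):
    """Raised for geometrically impossible maze configurations."""


def default_alley_length(circumradius: float, ideal_1_to_3: float = IDEAL_1_TO_3_M) -> float:
    """Alley length that calibrates the ideal 1→3 path to ``ideal_1_to_3`` metres.

    The ideal path runs alley-end(1) → vertex(1) → vertex(3) → alley-end(3);
    the middle leg is the pentagon chord spanning two vertex steps,
    2·R·sin(72°), so each alley contributes half the remainder.
    """
    chord = 2.0 * circumradius * math.sin(math.radians(144.0 / 2.0))
    length = (ideal_1_to_3 - chord) / 2.0
    if length <= 0:
        raise MazeConfigError("circumradius too large for the requested ideal path length")
    return length


@dataclass(frozen=True)
class MazeConfig:
    """Dimensions and options of the star maze.

    Parameters
    ----------
    circumradius : float
        Distance (m) from the pentagon centroid to each vertex.
    alley_length : float, optional
        Corridor length (m) from pentagon vertex to alley end.  Defaults to
        the value calibrated so that the ideal 1→3 path is 246 m.
    alley_width : float
        Corridor width (m); must be smaller than the pentagon edge.
    reward_capture_radius : float
        Radius (m) within which the invisible reward is captured.
    cue_visibility : {"cued", "bare"}
        Whether landmarks are present.
    landmark_labels : mapping (i, i+1) -> str
        One landmark per gap between adjacent alley ends.
    """

    circumradius: float = 8.0
    alley_length: Optional[float] = None
    alley_width: float = 4.0
    reward_capture_radius: float = 2.0
    cue_visibility: str = "cued"
    landmark_labels: Mapping[Tuple[int, int], str] = field(default_factory=lambda: dict(DEFAULT_LANDMARKS))

    n_alleys: int = N_ALLEYS  # fixed by the task; kept as a field for serialization

    def __post_init__(self) -> None:
        if self.n_alleys != N_ALLEYS:
            raise MazeConfigError("the star maze has exactly five alleys")
        if self.circumradius <= 0:
            raise MazeConfigError("circumradius must be positive")
        if self.alley_length is None:
            object.__setattr__(self, "alley_length", default_alley_length(self.circumradius))
        if self.alley_length <= 0:
            raise MazeConfigError("alley_length must be positive")
        if self.alley_width <= 0:
            raise MazeConfigError("alley_width must be positive")
        edge = 2.0 * self.circumradius * math.sin(math.pi / N_ALLEYS)
        if self.alley_width >= edge:
            raise MazeConfigError(
                f"alley_width {self.alley_width} must be smaller than the pentagon edge {edge:.3f}"
            )
        if self.reward_capture_radius <= 0:
            raise MazeConfigError("reward_capture_radius must be positive")
        if self.reward_capture_radius >= self.alley_length:
            raise MazeConfigError("reward_capture_radius must be smaller than the alley length")
        if self.cue_visibility not in ("cued", "bare"):
            raise MazeConfigError("cue_visibility must be 'cued' or 'bare'")

    def alley_heading_deg(self, alley: int) -> float:
        """Heading (deg CCW from +x) of alley ``alley`` (1-based); alley 1 is +y."""
        _check_alley(alley)
        return 90.0 + (alley - 1) * (360.0 / N_ALLEYS)

    def to_dict(self) -> dict:
        return {
            "circumradius": self.circumradius,
            "alley_length": self.alley_length,
            "alley_width": self.alley_width,
            "capture_radius": self.reward_capture_radius,
            "cue_visibility": self.cue_visibility,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MazeConfig":
        return cls(
            circumradius=float(d.get("circumradius", 8.0)),
            alley_length=(None if d.get("alley_length") is None else float(d["alley_length"])),
            alley_width=float(d.get("alley_width", 4.0)),
            reward_capture_radius=float(d.get("capture_radius", d.get("reward_capture_radius", 2.0))),
            cue_visibility=str(d.get("cue_visibility", "cued")),
        )


def _check_alley(alley: int) -> None:
    if not (isinstance(alley, (int, np.integer)) and 1 <= alley <= N_ALLEYS):
        raise ValueError(f"alley id must be an integer in 1..{N_ALLEYS}, got {alley!r}")


class Maze:
    """Built star maze: region polygons, reward/landmark coordinates, queries.

    Regions are the centre pentagon, the five alley corridors and the five
    alley-end (capture) zones; together with ``outside`` they partition the
    plane, with the more specific label winning where polygons touch.
    """

    def __init__(self, config: MazeConfig):
        self.config = config
        R, L, W = config.circumradius, config.alley_length, config.alley_width

        headings = np.array([math.radians(config.alley_heading_deg(i)) for i in range(1, N_ALLEYS + 1)])
        self.alley_units = np.column_stack([np.cos(headings), np.sin(headings)])  # (5, 2) radial units
        self.vertices = R * self.alley_units  # pentagon vertex of each alley
        self.alley_ends = (R + L) * self.alley_units
        self.reward_points = self.alley_ends.copy()

        self.center_polygon = Polygon(self.vertices)
        self.alley_polygons: List[Polygon] = []
        for i in range(N_ALLEYS):
            u = self.alley_units[i]
            n = np.array([-u[1], u[0]])  # left normal
            v0, v1 = self.vertices[i], self.alley_ends[i]
            half = 0.5 * W
            self.alley_polygons.append(
                Polygon([v0 + half * n, v1 + half * n, v1 - half * n, v0 - half * n])
            )
        r = config.reward_capture_radius
        self.alley_end_polygons = [
            self.alley_polygons[i].intersection(Point(self.reward_points[i]).buffer(r, quad_segs=32))
            for i in range(N_ALLEYS)
        ]

        self.landmarks: Dict[str, np.ndarray] = {}
        for (a, b), label in config.landmark_labels.items():
            self.landmarks[label] = 0.5 * (self.alley_ends[a - 1] + self.alley_ends[b - 1])

    # ------------------------------------------------------------------ queries

    def locate(self, point: Sequence[float]) -> str:
        """Region label of a planar point.

        Returns one of ``alley_end_i``, ``alley_i``, ``center`` or
        ``outside`` (most specific label first).
        """
        p = Point(float(point[0]), float(point[1]))
        for i in range(N_ALLEYS):
            if self.alley_end_polygons[i].intersects(p):
                return f"alley_end_{i + 1}"
        for i in range(N_ALLEYS):
            if self.alley_polygons[i].intersects(p):
                return f"alley_{i + 1}"
        if self.center_polygon.intersects(p):
            return "center"
        return "outside"

    def alley_depths(self, xy: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Vectorised corridor coordinates of sample points.

        Parameters
        ----------
        xy : (n, 2) array

        Returns
        -------
        depth : (n, 5) array
            Signed distance (m) along each alley axis measured from the
            pentagon vertex (0 at the vertex, ``alley_length`` at the end).
        inside : (n, 5) boolean array
            True where the point lies within the corridor rectangle.
        """
        xy = np.asarray(xy, dtype=float)
        rel = xy[:, None, :] - self.vertices[None, :, :]  # (n, 5, 2)
        depth = np.einsum("nij,ij->ni", rel, self.alley_units)
        lateral = rel[:, :, 0] * (-self.alley_units[:, 1]) + rel[:, :, 1] * self.alley_units[:, 0]
        inside = (
            (depth >= 0.0)
            & (depth <= self.config.alley_length)
            & (np.abs(lateral) <= 0.5 * self.config.alley_width)
        )
        return depth, inside

    def reward_point(self, alley: int) -> np.ndarray:
        _check_alley(alley)
        return self.reward_points[alley - 1]

    def alley_end(self, alley: int) -> np.ndarray:
        _check_alley(alley)
        return self.alley_ends[alley - 1]


def build_maze(config: Optional[MazeConfig] = None) -> Maze:
    """Build a :class:`Maze` from ``config`` (default configuration if omitted)."""
    return Maze(config or MazeConfig())


def locate(point: Sequence[float], maze: Maze) -> str:
    """Functional alias for :meth:`Maze.locate`."""
    return maze.locate(point)


# ---------------------------------------------------------------------- ideal path


@dataclass(frozen=True)
class IdealPath:
    """Shortest admissible path between two alley ends.

    ``length`` is the "ideal distance traveled" and ``min_rotation_deg`` the
    "minimum rotations" entering the distance-error and rotation-angle
    metrics.
    """

    start_alley: int
    goal_alley: int
    polyline: np.ndarray  # (k, 2)
    length: float
    min_rotation_deg: float


def polyline_length(polyline: np.ndarray) -> float:
    d = np.diff(np.asarray(polyline, dtype=float), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def polyline_rotation_deg(polyline: np.ndarray) -> float:
    """Total absolute heading change (deg) along a polyline.

    Zero-length segments are dropped before differencing headings; heading
    differences are wrapped to (−180°, 180°].
    """
    pts = np.asarray(polyline, dtype=float)
    d = np.diff(pts, axis=0)
    keep = np.hypot(d[:, 0], d[:, 1]) > 1e-12
    d = d[keep]
    if len(d) < 2:
        return 0.0
    headings = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    dh = np.diff(headings)
    dh = (dh + 180.0) % 360.0 - 180.0
    # a precise half-turn is a 180° rotation, not −180°
    return float(np.abs(dh).sum())


def ideal_path(start_alley: int, goal_alley: int, maze: Maze) -> IdealPath:
    """Ideal path from the end of ``start_alley`` to the end of ``goal_alley``.

    The path descends the start alley to its pentagon vertex, crosses the
    centre along the vertex-to-vertex chord (which stays inside the
    pentagon) and ascends the goal alley.  For ``start == goal`` (the
    turn-around needed when a test trial returns to its start alley) it is
    the out-and-back stub with a 180° turn.
    """
    _check_alley(start_alley)
    _check_alley(goal_alley)
    e_s = maze.alley_end(start_alley)
    v_s = maze.vertices[start_alley - 1]
    if start_alley == goal_alley:
        polyline = np.array([e_s, v_s, e_s])
        length = polyline_length(polyline)
        return IdealPath(start_alley, goal_alley, polyline, length, 180.0)
    e_g = maze.alley_end(goal_alley)
    v_g = maze.vertices[goal_alley - 1]
    polyline = np.array([e_s, v_s, v_g, e_g])
    return IdealPath(
        start_alley,
        goal_alley,
        polyline,
        polyline_length(polyline),
        polyline_rotation_deg(polyline),
    )


# ---------------------------------------------------------------------- protocol


@dataclass(frozen=True)
class TrialSpec:
    """Task definition of a single navigation trial."""

    trial_index: int  # 1-based position in the full schedule
    task: str  # "task1" | "task2"
    trial_type: str  # "training" | "test" | "compelled_AS" | "compelled_ES"
    start_alley: int
    reward_alleys: FrozenSet[int]
    cue_visibility: str = "cued"
    time_limit_s: float = 120.0
    training_number: Optional[int] = None  # 1..16 for training trials
    test_number: Optional[int] = None  # 1..5 for test trials

    def __post_init__(self) -> None:
        _check_alley(self.start_alley)
        if not self.reward_alleys:
            raise ValueError("reward_alleys must be non-empty")
        for a in self.reward_alleys:
            _check_alley(a)


#: 1-based schedule positions of the five interposed test trials in Task 1.
TASK1_TEST_POSITIONS = (6, 10, 14, 17, 21)
#: Start alleys of the four compelled-allocentric trials (alley 2 and 5, twice each).
COMPELLED_AS_STARTS = (2, 5, 2, 5)
N_TRAINING = 16
N_COMPELLED_ES = 3


def default_protocol(counterbalance_seed: int = 0) -> List[TrialSpec]:
    """The canonical Task 1 + Task 2 schedule.

    Task 1 is fixed: 16 training trials (start alley 1, reward alley 3)
    with five test trials (start alley 4, rewards in alleys 1 and 3)
    interposed at positions 6, 10, 14, 17 and 21.  Task 2 holds four
    compelled-allocentric trials (new start alleys 2 and 5, landmarks
    visible) and three compelled-egocentric trials (start alley 1, bare
    maze); their order is counterbalanced deterministically from
    ``counterbalance_seed``.
    """
    trials: List[TrialSpec] = []
    training_no = test_no = 0
    for idx in range(1, 22):
        if idx in TASK1_TEST_POSITIONS:
            test_no += 1
            trials.append(
                TrialSpec(idx, "task1", "test", 4, frozenset({1, 3}), "cued", test_number=test_no)
            )
        else:
            training_no += 1
            trials.append(
                TrialSpec(idx, "task1", "training", 1, frozenset({3}), "cued", training_number=training_no)
            )

    rng = np.random.default_rng(counterbalance_seed)
    kinds = ["compelled_AS"] * len(COMPELLED_AS_STARTS) + ["compelled_ES"] * N_COMPELLED_ES
    order = rng.permutation(len(kinds))
    as_starts = iter(COMPELLED_AS_STARTS)
    idx = 21
    for k in order:
        idx += 1
        kind = kinds[k]
        if kind == "compelled_AS":
            trials.append(
                TrialSpec(idx, "task2", "compelled_AS", next(as_starts), frozenset({3}), "cued")
            )
        else:
            trials.append(TrialSpec(idx, "task2", "compelled_ES", 1, frozenset({3}), "bare"))
    return trials


def protocol_by_index(protocol: Sequence[TrialSpec]) -> Dict[int, TrialSpec]:
    return {t.trial_index: t for t in protocol}
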