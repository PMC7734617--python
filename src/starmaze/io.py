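"""Reading and writing trajectories, session manifests and cohort tables.

The canonical trajectory dialect is a CSV with header ``time_s,x_m,y_m``;
a :class:`TrajectoryDialect` maps other column layouts onto it.  A cohort
is described by a YAML/JSON manifest listing participants, their metadata
(group, motor-severity levels, test z-scores) and per-trial trajectory
file paths.  The reader is strict (monotone time, numeric cells); the
writer emits a fixed-format canonical CSV so round trips are
byte-identical.  Missing trials are recorded as absent with a warning —
data gaps are expected (some participants never achieve stable success).
"""

from __future__ import annotations

import csv
import io as _stdio
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, IO, List, Mapping, Optional, Sequence, Union

import numpy as np
import yaml

__all__ = [
    "Trajectory",
    "TrajectoryDialect",
    "ParticipantSession",
    "Cohort",
    "TrajectoryFormatError",
    "TrajectoryValidationError",
    "ManifestError",
    "read_trajectory",
    "write_trajectory",
    "read_cohort",
    "write_cohort",
]

VALID_GROUPS = ("CP", "TD")


class TrajectoryFormatError(ValueError):
    """Malformed trajectory file (missing columns, wrong header)."""


class TrajectoryValidationError(ValueError):
    """Structurally valid file carrying invalid data (non-monotone time, too short)."""


class ManifestError(ValueError):
    """Invalid cohort manifest."""


@dataclass(frozen=True)
class TrajectoryDialect:
    """Column mapping from a foreign CSV layout onto the canonical one."""

    time_col: str = "time_s"
    x_col: str = "x_m"
    y_col: str = "y_m"
    delimiter: str = ","


CANONICAL = TrajectoryDialect()


@dataclass
class Trajectory:
    """Sampled planar position time series of one navigation trial."""

    time_s: np.ndarray
    x_m: np.ndarray
    y_m: np.ndarray
    sampling_rate_hz: float = 120.0
    trial_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x_m = np.asarray(self.x_m, dtype=float)
        self.y_m = np.asarray(self.y_m, dtype=float)
        if not (self.time_s.shape == self.x_m.shape == self.y_m.shape):
            raise TrajectoryValidationError("time, x and y must have equal lengths")
        if self.time_s.ndim != 1 or len(self.time_s) < 2:
            raise TrajectoryValidationError("a trajectory needs at least two samples")
        if not np.all(np.isfinite(self.time_s)) or not np.all(np.isfinite(self.xy)):
            raise TrajectoryValidationError("non-finite values in trajectory")
        if np.any(np.diff(self.time_s) <= 0):
            raise TrajectoryValidationError("time must be strictly increasing")

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x_m, self.y_m])

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class ParticipantSession:
    """One participant's metadata plus all recorded trials."""

    participant_id: str
    group: str
    sex: Optional[str] = None
    age_years: Optional[float] = None
    gmfcs: Optional[str] = None
    macs: Optional[str] = None
    raven_z: Optional[float] = None
    corsi_z: Optional[float] = None
    labyrinth_z: Optional[float] = None
    trials: Dict[int, Trajectory] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ManifestError(
                f"participant {self.participant_id!r}: unknown group {self.group!r} "
                f"(expected one of {VALID_GROUPS})"
            )


Cohort = List[ParticipantSession]


# ---------------------------------------------------------------------- trajectories


def read_trajectory(
    source: Union[str, Path, IO[str]],
    dialect: TrajectoryDialect = CANONICAL,
    sampling_rate_hz: float = 120.0,
    trial_index: Optional[int] = None,
) -> Trajectory:
    """Read and validate one trajectory CSV.

    Raises :class:`TrajectoryFormatError` when required columns are missing
    and :class:`TrajectoryValidationError` for non-monotone time,
    non-numeric cells or fewer than two samples.
    """
    if hasattr(source, "read"):
        return _read_stream(source, dialect, sampling_rate_hz, trial_index)
    with open(source, "r", newline="") as fh:
        return _read_stream(fh, dialect, sampling_rate_hz, trial_index)


def _read_stream(fh: IO[str], dialect, sampling_rate_hz, trial_index) -> Trajectory:
    reader = csv.DictReader(fh, delimiter=dialect.delimiter)
    cols = reader.fieldnames or []
    needed = (dialect.time_col, dialect.x_col, dialect.y_col)
    missing = [c for c in needed if c not in cols]
    if missing:
        raise TrajectoryFormatError(f"missing columns {missing}; found {cols}")
    t, x, y = [], [], []
    for lineno, row in enumerate(reader, start=2):
        try:
            t.append(float(row[dialect.time_col]))
            x.append(float(row[dialect.x_col]))
            y.append(float(row[dialect.y_col]))
        except (TypeError, ValueError) as exc:
            raise TrajectoryValidationError(f"non-numeric value on line {lineno}") from exc
    return Trajectory(np.array(t), np.array(x), np.array(y), sampling_rate_hz, trial_index)


def write_trajectory(traj: Trajectory, sink: Union[str, Path, IO[str]]) -> None:
    """Write the canonical, locale-independent CSV (6 decimal places)."""
    if len(traj) < 2:  # defensive: Trajectory already enforces this
        raise TrajectoryValidationError("refusing to write an empty trajectory")
    lines = ["time_s,x_m,y_m"]
    for t, x, y in zip(traj.time_s, traj.x_m, traj.y_m):
        lines.append(f"{t:.6f},{x:.6f},{y:.6f}")
    text = "\n".join(lines) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        Path(sink).write_text(text)


def trajectory_to_csv_text(traj: Trajectory) -> str:
    buf = _stdio.StringIO()
    write_trajectory(traj, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------- cohorts

_META_FIELDS = ("sex", "age_years", "gmfcs", "macs", "raven_z", "corsi_z", "labyrinth_z")


def read_cohort(
    manifest: Union[str, Path],
    dialect: TrajectoryDialect = CANONICAL,
) -> Cohort:
    """Load a cohort from a YAML/JSON manifest.

    Trajectory paths are resolved relative to the manifest's directory.
    A listed-but-absent trial index (no path) is logged as a warning and
    recorded as missing; a dangling file path is an error naming the
    participant and trial.
    """
    manifest = Path(manifest)
    text = manifest.read_text()
    data = json.loads(text) if manifest.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping) or "participants" not in data:
        raise ManifestError("manifest must be a mapping with a 'participants' list")
    base = manifest.parent
    cohort: Cohort = []
    for entry in data["participants"]:
        pid = str(entry.get("id", ""))
        if not pid:
            raise ManifestError("every participant needs an 'id'")
        if "group" not in entry:
            raise ManifestError(f"participant {pid!r}: missing group label")
        meta = {k: entry.get(k) for k in _META_FIELDS}
        session = ParticipantSession(pid, str(entry["group"]), **meta)
        for key, rel in (entry.get("trials") or {}).items():
            idx = int(key)
            if rel is None:
                warnings.warn(f"participant {pid}: trial {idx} listed without data; treated as missing")
                continue
            path = base / rel
            if not path.exists():
                raise FileNotFoundError(f"participant {pid}, trial {idx}: trajectory file {path} not found")
            session.trials[idx] = read_trajectory(path, dialect=dialect, trial_index=idx)
        cohort.append(session)
    return cohort


def write_cohort(
    cohort: Cohort,
    directory: Union[str, Path],
    protocol_seed: int = 0,
    maze_config: Optional[Mapping] = None,
) -> Path:
    """Write a cohort directory (manifest.yaml + one CSV per trial).

    Returns the manifest path.  Output is deterministic: fixed file naming,
    fixed float formatting, participants in given order.
    """
    directory = Path(directory)
    (directory / "trajectories").mkdir(parents=True, exist_ok=True)
    entries = []
    for session in cohort:
        trials = {}
        for idx in sorted(session.trials):
            rel = f"trajectories/{session.participant_id}_trial{idx:02d}.csv"
            write_trajectory(session.trials[idx], directory / rel)
            trials[idx] = rel
        entry = {"id": session.participant_id, "group": session.group, "trials": trials}
        for k in _META_FIELDS:
            v = getattr(session, k)
            if v is not None:
                entry[k] = float(v) if isinstance(v, (int, float, np.floating)) else v
        entries.append(entry)
    doc = {
        "protocol": {"counterbalance_seed": int(protocol_seed)},
        "participants": entries,
    }
    if maze_config is not None:
        doc["maze"] = dict(maze_config)
    out = directory / "manifest.yaml"
    out.write_text(yaml.safe_dump(doc, sort_keys=True))
    return out
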