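"""Agent-based synthetic trajectory generator for the star-maze protocol.

Every pipeline stage can be exercised without recorded data by simulating
a cohort of navigating agents over the full Task 1 + Task 2 schedule.

Behavioural contract
--------------------
* An **egocentric** agent replays a start-relative motor sequence.  The
  trained route (start alley 1 → reward alley 3) is the offset +2 alleys,
  so from the test-trial start (alley 4) it lands in alley 1, and from the
  compelled-allocentric starts (alleys 2 and 5) it lands in alleys 4 and 2
  and misses the reward.  Landmarks are irrelevant to it, so it still
  succeeds in the bare maze.
* An **allocentric** agent steers to the landmark-defined goal (alley 3)
  from any cued start; stripped of landmarks (bare maze) it degrades to
  lost behaviour.
* A **shifter** holds both competences and alternates between them on
  test trials (switching with probability ``switch_prob`` per test trial;
  the default 1.0 alternates deterministically so a noiseless shifter is
  recovered with certainty).
* A **lost** agent wanders: it repeatedly picks a uniformly random other
  alley and walks partway in (committing to the far end with probability
  ``lost_commit_prob``), with no reward memory.

Learning is an error probability decaying geometrically over training
trials, p(t) = initial_error_prob · (1 − learning_rate)^(t−1).  On an
error the agent detours through one or more wrong alleys (partway — it
knows they are not the goal) before resuming, or runs out of time.  Motion
is waypoint steering sampled at the nominal rate with per-trial lognormal
speed and temporally smoothed Gaussian path jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .io import Cohort, ParticipantSession, Trajectory
from .maze import Maze, MazeConfig, TrialSpec, build_maze, default_protocol

__all__ = [
    "AgentConfig",
    "GroupConfig",
    "CohortConfig",
    "AgentState",
    "simulate_trial",
    "simulate_session",
    "simulate_cohort",
    "study_cohort_config",
    "recovery_cohort_config",
]

STRATEGIES = ("egocentric", "allocentric", "shifter", "lost")

#: Trained egocentric motor sequence expressed as an alley offset: the
#: training route runs from alley 1 to alley 3, i.e. +2 alleys (mod 5).
EGO_OFFSET = 2
#: Landmark-defined goal learnt during training.
ALLO_GOAL = 3


class SimulationConfigError(ValueError):
    """Invalid simulator configuration (bad mixture, probabilities, speeds)."""


@dataclass(frozen=True)
class AgentConfig:
    """Behavioural parameters of one simulated navigator.

    Defaults are the generator's reference noise condition: path jitter of
    0.5 m, an initial error probability of 0.6 decaying by 50% per
    training trial, and walking speeds matching the stable-phase trial
    times of the task (~30 s for the 246 m ideal route).
    """

    strategy: str = "egocentric"
    learning_rate: float = 0.5  # per-trial decay of the error probability
    initial_error_prob: float = 0.6
    path_jitter_sd: float = 0.5  # m, pointwise sd of the smoothed jitter
    jitter_smooth_s: float = 1.0  # temporal smoothing scale of the jitter
    speed_mean: float = 8.5  # m/s (virtual units; the task is fast)
    speed_sd: float = 1.5
    switch_prob: float = 1.0  # shifter: probability of switching per test trial
    detour_depth: Tuple[float, float] = (0.25, 0.75)  # error detours peek partway in
    lost_commit_prob: float = 0.3  # lost agent: chance of walking to the far end
    lost_depth: Tuple[float, float] = (0.3, 0.8)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise SimulationConfigError(f"unknown strategy {self.strategy!r}")
        for name in ("learning_rate", "initial_error_prob", "switch_prob", "lost_commit_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimulationConfigError(f"{name} must be in [0, 1], got {v}")
        if self.learning_rate == 0.0:
            raise SimulationConfigError("learning_rate must be positive")
        if self.speed_mean <= 0 or self.speed_sd < 0:
            raise SimulationConfigError("speeds must be positive")
        if self.path_jitter_sd < 0:
            raise SimulationConfigError("path_jitter_sd must be non-negative")


@dataclass
class AgentState:
    """Mutable per-session state: config plus learning progress."""

    config: AgentConfig
    training_count: int = 0  # completed training trials
    shifter_mode: Optional[str] = None  # "AS" | "ES"

    @property
    def error_prob(self) -> float:
        c = self.config
        return c.initial_error_prob * (1.0 - c.learning_rate) ** self.training_count


@dataclass(frozen=True)
class GroupConfig:
    """Size, strategy mixture and base behaviour of one simulated group."""

    n: int
    mixture: Mapping[str, float]
    agent: AgentConfig = field(default_factory=AgentConfig)
    aptitude_mean: float = 0.0  # group shift of the latent learning aptitude
    aptitude_lr_slope: float = 0.18  # learning-rate change per aptitude unit

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SimulationConfigError("group size must be at least 1")
        total = float(sum(self.mixture.values()))
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise SimulationConfigError(f"mixture weights must sum to 1, got {total}")
        unknown = set(self.mixture) - set(STRATEGIES)
        if unknown:
            raise SimulationConfigError(f"unknown strategies in mixture: {sorted(unknown)}")


#: Planted monotone links from the latent aptitude to the test z-scores,
#: as (intercept, slope, noise_sd): faster learners score higher on the
#: visuospatial tests, nearly independently on the general-cognition test.
DEFAULT_ZSCORE_MODEL: Mapping[str, Tuple[float, float, float]] = {
    "corsi_z": (0.2, 0.55, 0.5),
    "labyrinth_z": (0.3, 0.50, 0.7),
    "raven_z": (0.0, 0.15, 1.0),
}


@dataclass(frozen=True)
class CohortConfig:
    """Full synthetic-cohort recipe (groups, protocol seed, z-score model)."""

    groups: Mapping[str, GroupConfig]
    seed: int = 0
    protocol_seed: int = 0
    sampling_rate_hz: float = 120.0
    zscore_model: Mapping[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ZSCORE_MODEL)
    )
    maze: MazeConfig = field(default_factory=MazeConfig)


def study_cohort_config(seed: int = 0) -> CohortConfig:
    """Cohort emulating the pilot study: 15 CP vs 13 TD participants.

    Strategy mixtures follow the observed shares (TD 54% allocentric / 31%
    egocentric / 15% shifter; CP 27/53/7 plus 13% lacking), and the CP
    group carries a lower mean learning aptitude so that it stabilizes
    later.
    """
    td_agent = AgentConfig(learning_rate=0.65)
    cp_agent = AgentConfig(learning_rate=0.45)
    return CohortConfig(
        groups={
            "TD": GroupConfig(
                n=13,
                mixture={"allocentric": 0.54, "egocentric": 0.31, "shifter": 0.15},
                agent=td_agent,
                aptitude_mean=0.5,
            ),
            "CP": GroupConfig(
                n=15,
                mixture={"allocentric": 0.27, "egocentric": 0.53, "shifter": 0.07, "lost": 0.13},
                agent=cp_agent,
                aptitude_mean=-0.5,
            ),
        },
        seed=seed,
    )


def recovery_cohort_config(n: int = 200, seed: int = 0, noiseless: bool = False) -> CohortConfig:
    """Single-group cohort for parameter-recovery experiments.

    The default mixture holds the two strategy-bearing classes in equal
    shares with minorities of shifters and lost wanderers.  ``noiseless``
    zeroes jitter and the error probability; it applies to strategy-bearing
    agents only, since the lost agent's randomness is its behaviour, not
    noise, so the noiseless mixture drops it.
    """
    agent = AgentConfig(path_jitter_sd=0.0, initial_error_prob=0.0) if noiseless else AgentConfig()
    mixture = (
        {"egocentric": 0.45, "allocentric": 0.45, "shifter": 0.10}
        if noiseless
        else {"egocentric": 0.40, "allocentric": 0.40, "shifter": 0.10, "lost": 0.10}
    )
    return CohortConfig(
        groups={"TD": GroupConfig(n=n, mixture=mixture, agent=agent, aptitude_lr_slope=0.0)},
        seed=seed,
    )


# ------------------------------------------------------------------ trial planning


def _other_alleys(alley: int) -> List[int]:
    return [a for a in range(1, 6) if a != alley]


def _ego_target(start: int) -> int:
    return (start - 1 + EGO_OFFSET) % 5 + 1


def _plan_legs(
    state: AgentState, spec: TrialSpec, maze: Maze, rng: np.random.Generator
) -> List[Tuple[int, float]]:
    """Ordered (alley, depth_fraction) legs of one trial.

    A depth fraction of 1.0 reaches the alley end (and captures a reward
    placed there); smaller fractions peek partway in and return.  The legs
    encode intent only — capture, truncation at the time limit and all
    metrics are resolved from the sampled trajectory.
    """
    c = state.config
    strategy = c.strategy
    if strategy == "shifter":
        if spec.trial_type == "test":
            if state.shifter_mode is None:
                state.shifter_mode = "AS" if rng.random() < 0.5 else "ES"
            elif rng.random() < c.switch_prob:
                state.shifter_mode = "ES" if state.shifter_mode == "AS" else "AS"
            strategy = "allocentric" if state.shifter_mode == "AS" else "egocentric"
        elif spec.trial_type == "compelled_AS":
            strategy = "allocentric"
        else:  # training, compelled_ES
            strategy = "egocentric"

    if strategy == "allocentric" and spec.cue_visibility == "bare":
        strategy = "lost"  # no landmarks, no map

    if strategy == "lost":
        return _wander_legs(state, spec, maze, rng)

    target = ALLO_GOAL if strategy == "allocentric" else _ego_target(spec.start_alley)

    legs: List[Tuple[int, float]] = []
    if rng.random() < state.error_prob:
        lo, hi = c.detour_depth
        n_detours = int(min(rng.geometric(0.5), 3))
        pool = _other_alleys(spec.start_alley)
        for alley in rng.choice(pool, size=n_detours, replace=False):
            legs.append((int(alley), float(rng.uniform(lo, hi))))
    legs.append((target, 1.0))
    return legs


def _wander_legs(
    state: AgentState, spec: TrialSpec, maze: Maze, rng: np.random.Generator
) -> List[Tuple[int, float]]:
    """Memoryless random wandering until a reward end is reached or time runs out."""
    c = state.config
    budget = c.speed_mean * spec.time_limit_s * 1.5  # truncated by time later anyway
    spent = 0.0
    legs: List[Tuple[int, float]] = []
    current = spec.start_alley
    L = maze.config.alley_length
    while spent < budget:
        alley = int(rng.choice(_other_alleys(current)))
        depth = 1.0 if rng.random() < c.lost_commit_prob else float(rng.uniform(*c.lost_depth))
        legs.append((alley, depth))
        spent += 2.0 * L * depth + 10.0
        if depth == 1.0 and alley in spec.reward_alleys:
            break
        current = alley
    return legs


# ------------------------------------------------------------------ trajectory synthesis


def _waypoints(
    legs: Sequence[Tuple[int, float]], spec: TrialSpec, maze: Maze
) -> Tuple[np.ndarray, bool]:
    """Waypoint polyline through the maze; True when it ends at a reward point.

    Movement follows corridors and vertex-to-vertex chords (which stay
    inside the pentagon).  A full-depth leg into a reward alley terminates
    the polyline at the reward coordinate.
    """
    L = maze.config.alley_length
    pts: List[np.ndarray] = [maze.alley_end(spec.start_alley)]
    current = spec.start_alley
    captured = False
    for alley, depth in legs:
        pts.append(maze.vertices[current - 1])
        if alley != current:
            pts.append(maze.vertices[alley - 1])
        tip = maze.vertices[alley - 1] + depth * L * maze.alley_units[alley - 1]
        pts.append(tip)
        current = alley
        if depth >= 1.0 and alley in spec.reward_alleys:
            captured = True
            break
    return np.asarray(pts, dtype=float), captured


def _sample_polyline(
    pts: np.ndarray, speed: float, rate: float, time_limit: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Constant-speed sampling of a waypoint polyline at ``rate`` Hz."""
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    keep = seg_len > 1e-12
    pts = np.vstack([pts[:1], pts[1:][keep]])
    arc = np.concatenate([[0.0], np.cumsum(seg_len[keep])])
    total = float(arc[-1])
    duration = min(total / speed, time_limit)
    n = max(int(np.floor(duration * rate)), 1)
    t = np.arange(n + 1) / rate
    s = np.minimum(t * speed, total)
    x = np.interp(s, arc, pts[:, 0])
    y = np.interp(s, arc, pts[:, 1])
    return t, np.column_stack([x, y])


def _add_jitter(
    xy: np.ndarray, sd: float, smooth_s: float, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Temporally smoothed Gaussian positional jitter (body sway, steering noise).

    The jitter tapers to zero over the final two seconds: a navigator
    steering at a goal homes onto it, so the planned endpoint is reached
    exactly rather than displaced by sway.
    """
    if sd <= 0 or len(xy) < 8:
        return xy
    white = rng.standard_normal(xy.shape)
    sigma = max(smooth_s * rate, 1.0)
    smooth = gaussian_filter1d(white, sigma=sigma, axis=0, mode="reflect")
    col_sd = smooth.std(axis=0)
    col_sd[col_sd == 0] = 1.0
    noise = smooth / col_sd * sd
    k = min(int(2.0 * rate), len(xy))
    envelope = np.ones(len(xy))
    envelope[len(xy) - k :] = np.linspace(1.0, 0.0, k)
    return xy + noise * envelope[:, None]


def simulate_trial(
    state: AgentState, spec: TrialSpec, maze: Maze, rng: np.random.Generator,
    sampling_rate_hz: float = 120.0,
) -> Tuple[Trajectory, Dict[str, object]]:
    """One trial's trajectory plus ground-truth annotations.

    Returns ``(trajectory, truth)`` where truth records the planned legs,
    whether the plan reached a reward in time, and the error-probability at
    trial time.  Learning state (training counter) is advanced for
    training trials.
    """
    c = state.config
    legs = _plan_legs(state, spec, maze, rng)
    pts, planned_capture = _waypoints(legs, spec, maze)

    sigma_ln = math.sqrt(math.log(1.0 + (c.speed_sd / c.speed_mean) ** 2))
    mu_ln = math.log(c.speed_mean) - 0.5 * sigma_ln**2
    speed = float(rng.lognormal(mu_ln, sigma_ln)) if c.speed_sd > 0 else c.speed_mean

    t, xy = _sample_polyline(pts, speed, sampling_rate_hz, spec.time_limit_s)
    seg = np.diff(pts, axis=0)
    total_len = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    in_time = planned_capture and (total_len / speed) <= spec.time_limit_s
    xy = _add_jitter(xy, c.path_jitter_sd, c.jitter_smooth_s, sampling_rate_hz, rng)

    traj = Trajectory(t, xy[:, 0], xy[:, 1], sampling_rate_hz, spec.trial_index)
    truth = {
        "trial_index": spec.trial_index,
        "trial_type": spec.trial_type,
        "legs": legs,
        "planned_success": bool(in_time),
        "error_prob": state.error_prob,
        "speed_m_s": speed,
    }
    if spec.trial_type == "training":
        state.training_count += 1
    return traj, truth


# ------------------------------------------------------------------ cohorts


def _draw_agent(
    group: GroupConfig, rng: np.random.Generator
) -> Tuple[AgentConfig, float]:
    """Sample one agent: strategy from the mixture, aptitude-shifted learning rate."""
    strategies = sorted(group.mixture)
    weights = np.array([group.mixture[s] for s in strategies])
    strategy = str(rng.choice(strategies, p=weights / weights.sum()))
    aptitude = float(rng.normal(group.aptitude_mean, 1.0))
    lr = float(np.clip(group.agent.learning_rate + group.aptitude_lr_slope * aptitude, 0.05, 0.95))
    return replace(group.agent, strategy=strategy, learning_rate=lr), aptitude


def simulate_session(
    participant_id: str,
    group_name: str,
    agent: AgentConfig,
    aptitude: float,
    config: CohortConfig,
    maze: Maze,
    protocol: Sequence[TrialSpec],
    rng: np.random.Generator,
) -> Tuple[ParticipantSession, pd.DataFrame]:
    """Simulate one participant over the full protocol."""
    zscores = {}
    for name, (a, b, sd) in config.zscore_model.items():
        zscores[name] = float(a + b * aptitude + rng.normal(0.0, sd))
    session = ParticipantSession(participant_id, group_name, **zscores)
    state = AgentState(agent)
    truths = []
    for spec in protocol:
        traj, truth = simulate_trial(state, spec, maze, rng, config.sampling_rate_hz)
        session.trials[spec.trial_index] = traj
        truth.update(
            participant_id=participant_id,
            group=group_name,
            true_strategy=agent.strategy,
            learning_rate=agent.learning_rate,
            aptitude=aptitude,
        )
        truths.append(truth)
    return session, pd.DataFrame(truths)


def simulate_cohort(config: CohortConfig) -> Tuple[Cohort, pd.DataFrame]:
    """Simulate a full cohort; reproducible from ``config.seed``.

    Returns the cohort and a truth table with one row per trial carrying
    the generating strategy, the planned outcome and agent parameters.
    Use :func:`starmaze.io.write_cohort` to emit it to disk.
    """
    maze = build_maze(config.maze)
    protocol = default_protocol(config.protocol_seed)
    rng = np.random.default_rng(config.seed)
    cohort: Cohort = []
    truths = []
    for group_name in sorted(config.groups):
        group = config.groups[group_name]
        for j in range(group.n):
            pid = f"{group_name}{j + 1:03d}"
            agent, aptitude = _draw_agent(group, rng)
            session, truth = simulate_session(
                pid, group_name, agent, aptitude, config, maze, protocol, rng
            )
            cohort.append(session)
            truths.append(truth)
    return cohort, pd.concat(truths, ignore_index=True)


def iter_simulated_sessions(
    config: CohortConfig,
) -> Iterator[Tuple[ParticipantSession, pd.DataFrame]]:
    """Stream sessions one at a time (trajectories can be dropped after use).

    Yields exactly the same sessions as :func:`simulate_cohort` for the
    same config.
    """
    maze = build_maze(config.maze)
    protocol = default_protocol(config.protocol_seed)
    rng = np.random.default_rng(config.seed)
    for group_name in sorted(config.groups):
        group = config.groups[group_name]
        for j in range(group.n):
            pid = f"{group_name}{j + 1:03d}"
            agent, aptitude = _draw_agent(group, rng)
            yield simulate_session(pid, group_name, agent, aptitude, config, maze, protocol, rng)
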