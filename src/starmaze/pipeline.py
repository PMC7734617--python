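"""End-to-end orchestration: cohort → metrics → classification → knee → stats.

The pipeline's central data structures are tidy pandas frames:

* the **metrics frame**: one row per participant × trial with the seven
  per-trial parameters plus schedule annotations,
* the **participants frame**: one row per participant with metadata and
  z-scores,
* the **classification frame**: one row per participant with the five
  test-trial labels, the overall strategy, the learning onset and the
  compelled success rates.

``run_pipeline`` chains the stages, writes every artifact (CSV/JSON/PNG)
into an output directory and is deterministic given its inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import learning, stats, strategy
from .io import Cohort, ParticipantSession, read_cohort, write_cohort
from .maze import Maze, MazeConfig, TrialSpec, build_maze, default_protocol, protocol_by_index
from .metrics import compute_trial_metrics
from .simulate import CohortConfig, simulate_cohort, study_cohort_config

logger = logging.getLogger("starmaze")

__all__ = [
    "RunConfig",
    "PipelineError",
    "session_metrics_rows",
    "cohort_metrics_frame",
    "participants_frame",
    "classification_frame",
    "run_pipeline",
    "make_report",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ------------------------------------------------------------------ frames


def session_metrics_rows(
    session: ParticipantSession,
    maze: Maze,
    protocol: Sequence[TrialSpec],
    depth_fraction: float = 0.10,
    min_step: float = 0.05,
) -> List[dict]:
    """Per-trial metric rows for one participant (missing trials skipped)."""
    by_index = protocol_by_index(protocol)
    rows = []
    for idx, spec in by_index.items():
        traj = session.trials.get(idx)
        if traj is None:
            continue
        m = compute_trial_metrics(traj, spec, maze, depth_fraction=depth_fraction, min_step=min_step)
        rows.append(
            {
                "participant_id": session.participant_id,
                "group": session.group,
                "trial_index": idx,
                "task": spec.task,
                "trial_type": spec.trial_type,
                "training_number": spec.training_number,
                "test_number": spec.test_number,
                "start_alley": spec.start_alley,
                "success": m.success,
                "time_s": m.duration_s,
                "time_to_reward_s": m.time_to_reward_s,
                "reached_alley": m.reached_alley,
                "visited_order": "-".join(map(str, m.visited_alleys)),
                "visited_n": m.visited_n,
                "tpl_m": m.tpl_m,
                "mean_speed_m_s": m.mean_speed_m_s,
                "de_pct": m.de_pct,
                "ra_deg": m.ra_deg,
                "notes": "; ".join(m.notes),
            }
        )
    return rows


def cohort_metrics_frame(
    cohort: Cohort,
    maze: Maze,
    protocol: Sequence[TrialSpec],
    depth_fraction: float = 0.10,
    min_step: float = 0.05,
) -> pd.DataFrame:
    """Tidy metrics frame over a whole cohort."""
    rows: List[dict] = []
    for session in cohort:
        rows.extend(session_metrics_rows(session, maze, protocol, depth_fraction, min_step))
    if not rows:
        raise PipelineError("metrics: cohort contains no trials")
    return pd.DataFrame(rows)


def participants_frame(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for s in cohort:
        rows.append(
            {
                "participant_id": s.participant_id,
                "group": s.group,
                "sex": s.sex,
                "age_years": s.age_years,
                "gmfcs": s.gmfcs,
                "macs": s.macs,
                "raven_z": s.raven_z,
                "corsi_z": s.corsi_z,
                "labyrinth_z": s.labyrinth_z,
                "n_trials": len(s.trials),
            }
        )
    return pd.DataFrame(rows)


def classification_frame(
    metrics_df: pd.DataFrame,
    protocol: Sequence[TrialSpec],
    consecutive_threshold: int = 4,
    onset_bins=strategy.DEFAULT_ONSET_BINS,
) -> pd.DataFrame:
    """Per-participant strategy labels, learning onset and compelled rates.

    Test trials absent from the metrics frame are treated as NoEfficient
    (no evidence of an efficient route); missing training trials count as
    failures for the onset.
    """
    by_index = protocol_by_index(protocol)
    test_indices = [t.trial_index for t in protocol if t.trial_type == "test"]
    training_indices = [t.trial_index for t in protocol if t.trial_type == "training"]
    compelled = [t for t in protocol if t.trial_type.startswith("compelled")]

    rows = []
    for pid, sub in metrics_df.groupby("participant_id", sort=True):
        sub = sub.set_index("trial_index")
        labels = []
        for idx in test_indices:
            if idx in sub.index:
                r = sub.loc[idx]
                lab = (
                    strategy.AS
                    if (r["success"] and r["visited_n"] == 2 and r["reached_alley"] == strategy.AS_GOAL_ALLEY)
                    else strategy.ES
                    if (r["success"] and r["visited_n"] == 2 and r["reached_alley"] == strategy.ES_GOAL_ALLEY)
                    else strategy.NO_EFFICIENT
                )
            else:
                lab = strategy.NO_EFFICIENT
            labels.append(lab)
        overall = strategy.classify_participant(labels, consecutive_threshold=consecutive_threshold)

        flags = [
            bool(sub.loc[idx, "success"]) if idx in sub.index else False for idx in training_indices
        ]
        onset, onset_bin = strategy.learning_onset(flags, bins=onset_bins)

        as_n = as_tot = es_n = es_tot = 0
        for spec in compelled:
            if spec.trial_index not in sub.index:
                continue
            r = sub.loc[spec.trial_index]
            ok = bool(r["success"] and r["visited_n"] == 2)
            if spec.trial_type == "compelled_AS":
                as_n, as_tot = as_n + ok, as_tot + 1
            else:
                es_n, es_tot = es_n + ok, es_tot + 1

        row = {
            "participant_id": pid,
            "group": sub["group"].iloc[0],
            "strategy": overall.label,
            "onset": onset,
            "onset_bin": onset_bin,
            "compelled_as_pct": 100.0 * as_n / as_tot if as_tot else np.nan,
            "compelled_es_pct": 100.0 * es_n / es_tot if es_tot else np.nan,
        }
        for j, lab in enumerate(labels, start=1):
            row[f"test_{j}"] = lab
        rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ run config / pipeline


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one of ``cohort_dir`` (manifest-described cohort on disk) or
    ``simulate`` (synthetic cohort recipe) must be given.
    """

    out_dir: Union[str, Path]
    cohort_dir: Optional[Union[str, Path]] = None
    simulate: Optional[CohortConfig] = None
    maze: MazeConfig = field(default_factory=MazeConfig)
    protocol_seed: int = 0
    depth_fraction: float = 0.10
    min_step: float = 0.05
    alpha_stable: float = 0.05
    alpha_change: float = 0.05
    make_figures: bool = True
    groups: Tuple[str, str] = ("CP", "TD")

    def __post_init__(self) -> None:
        if (self.cohort_dir is None) == (self.simulate is None):
            raise PipelineError("config: exactly one of cohort_dir or simulate must be set")
        if self.cohort_dir is not None and not Path(self.cohort_dir).exists():
            raise PipelineError(f"config: cohort directory {self.cohort_dir} does not exist")


def _load_inputs(config: RunConfig) -> Tuple[Cohort, Maze, Sequence[TrialSpec], Optional[pd.DataFrame]]:
    if config.simulate is not None:
        cohort, truth = simulate_cohort(config.simulate)
        maze = build_maze(config.simulate.maze)
        protocol = default_protocol(config.simulate.protocol_seed)
        return cohort, maze, protocol, truth
    cohort_dir = Path(config.cohort_dir)
    manifest = cohort_dir / "manifest.yaml"
    if not manifest.exists():
        manifest = cohort_dir / "manifest.json"
    if not manifest.exists():
        raise PipelineError(f"load: no manifest.yaml/json under {cohort_dir}")
    doc = yaml.safe_load(manifest.read_text())
    maze_cfg = MazeConfig.from_dict(doc.get("maze", {})) if doc.get("maze") else config.maze
    seed = int(doc.get("protocol", {}).get("counterbalance_seed", config.protocol_seed))
    cohort = read_cohort(manifest)
    return cohort, build_maze(maze_cfg), default_protocol(seed), None


def run_pipeline(config: RunConfig) -> Dict[str, Path]:
    """Run every stage and write the report bundle; returns artifact paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, Path] = {}

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("load")
        cohort, maze, protocol, truth = _load_inputs(config)
    except (OSError, ValueError) as exc:
        raise PipelineError(f"load: {exc}") from exc

    _stage("metrics")
    metrics_df = cohort_metrics_frame(
        cohort, maze, protocol, config.depth_fraction, config.min_step
    )
    participants = participants_frame(cohort)
    artifacts["metrics"] = out / "metrics.csv"
    metrics_df.to_csv(artifacts["metrics"], index=False, float_format="%.6f")
    artifacts["participants"] = out / "participants.csv"
    participants.to_csv(artifacts["participants"], index=False, float_format="%.6f")
    if truth is not None:
        artifacts["truth"] = out / "truth.csv"
        truth.drop(columns=["legs"]).to_csv(artifacts["truth"], index=False, float_format="%.6f")

    empty = set(participants["participant_id"]) - set(metrics_df["participant_id"])
    for pid in sorted(empty):
        logger.warning("participant %s has no usable trials", pid)

    _stage("classify")
    classes = classification_frame(metrics_df, protocol)
    artifacts["classification"] = out / "classification.csv"
    classes.to_csv(artifacts["classification"], index=False, float_format="%.6f")

    _stage("learning")
    present_groups = [g for g in config.groups if (metrics_df["group"] == g).any()]
    knee_by_group: Dict[str, Optional[int]] = {}
    knee_report: Dict[str, object] = {}
    curves_rows = []
    for g in present_groups:
        mats = learning.training_matrices(metrics_df, g)
        try:
            res = learning.detect_knee(mats, config.alpha_stable, config.alpha_change)
        except ValueError as exc:
            raise PipelineError(f"learning: group {g}: {exc}") from exc
        knee_by_group[g] = res.knee
        knee_report[g] = {
            "knee": res.knee,
            "friedman_p": res.friedman_p,
            "wilcoxon_p": res.wilcoxon_p,
            "candidates": res.candidates.to_dict(orient="records"),
        }
        for metric in learning.LEARNING_METRICS:
            curve = learning.group_learning_curves(metrics_df, g, metric)
            for t, med, iqr in zip(curve.trials, curve.median, curve.iqr):
                curves_rows.append(
                    {"group": g, "metric": metric, "training_number": int(t),
                     "median": med, "iqr": iqr}
                )
    artifacts["knee"] = out / "knee.json"
    artifacts["knee"].write_text(json.dumps(knee_report, indent=2, default=_json_default))
    curves = pd.DataFrame(curves_rows)
    artifacts["learning_curves"] = out / "learning_curves.csv"
    curves.to_csv(artifacts["learning_curves"], index=False, float_format="%.6f")

    _stage("stats")
    stats_report: Dict[str, object] = {}
    if len(present_groups) == 2 and all(knee_by_group[g] is not None for g in present_groups):
        knees = {g: int(knee_by_group[g]) for g in present_groups}
        stats_report["stable_table"] = learning.stable_performance_table(
            metrics_df, knees, maze, groups=tuple(present_groups)
        ).to_dict(orient="records")
        stats_report["navigation"] = [
            dataclasses.asdict(c)
            for c in stats.compare_navigation(metrics_df, knees, classes, groups=tuple(present_groups))
        ]
        stats_report["correlations"] = [
            dataclasses.asdict(c)
            for c in stats.learning_phase_correlations(metrics_df, participants, knees)
        ]
    if len(present_groups) == 2:
        try:
            stats_report["demographics"] = [
                dataclasses.asdict(c)
                for c in stats.compare_demographics(participants, groups=tuple(present_groups))
            ]
        except ValueError:
            pass
        n_by_group = participants.groupby("group")["participant_id"].count()
        stats_report["posthoc_power_d1_onetailed"] = stats.posthoc_power(
            int(n_by_group.iloc[0]), int(n_by_group.iloc[1]), d=1.0, alpha=0.05, tails=1
        )
    artifacts["stats"] = out / "stats.json"
    artifacts["stats"].write_text(json.dumps(stats_report, indent=2, default=_json_default))

    if config.make_figures:
        _stage("figures")
        artifacts.update(_make_figures(out, curves, classes, present_groups))

    _stage("done")
    return artifacts


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


GROUP_COLORS = {"CP": "tab:red", "TD": "tab:blue"}


def _make_figures(out: Path, curves: pd.DataFrame, classes: pd.DataFrame, groups) -> Dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    artifacts: Dict[str, Path] = {}

    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    titles = {"visited_n": "Visited alleys (#)", "tpl_m": "TPL (m)",
              "de_pct": "DE (%)", "ra_deg": "RA (deg)"}
    for ax, metric in zip(axes.ravel(), learning.LEARNING_METRICS):
        for g in groups:
            sub = curves[(curves["group"] == g) & (curves["metric"] == metric)]
            color = GROUP_COLORS.get(g, None)
            ax.plot(sub["training_number"], sub["median"], marker="o", label=g, color=color)
            ax.fill_between(
                sub["training_number"],
                sub["median"] - sub["iqr"] / 2,
                sub["median"] + sub["iqr"] / 2,
                alpha=0.15,
                color=color,
            )
        ax.set_title(titles.get(metric, metric))
        ax.set_xlabel("training trial")
    axes[0, 0].legend()
    fig.suptitle("Learning curves (median ± IQR/2)")
    fig.tight_layout()
    artifacts["fig_learning"] = out / "learning_curves.png"
    fig.savefig(artifacts["fig_learning"], dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, len(groups), figsize=(5 * len(groups), 4))
    axes = np.atleast_1d(axes)
    for ax, g in zip(axes, groups):
        counts = classes[classes["group"] == g]["strategy"].value_counts()
        if counts.sum():
            ax.pie(counts.values, labels=counts.index, autopct="%1.0f%%")
        ax.set_title(f"{g} strategies")
    artifacts["fig_strategies"] = out / "strategy_pie.png"
    fig.savefig(artifacts["fig_strategies"], dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    width = 0.35
    xs = np.arange(2)
    for k, g in enumerate(groups):
        sub = classes[classes["group"] == g]
        means = [sub["compelled_as_pct"].mean(), sub["compelled_es_pct"].mean()]
        ax.bar(xs + k * width, means, width, label=g, color=GROUP_COLORS.get(g))
    ax.set_xticks(xs + width / 2)
    ax.set_xticklabels(["compelled AS", "compelled ES"])
    ax.set_ylabel("success (%)")
    ax.legend()
    artifacts["fig_compelled"] = out / "compelled_success.png"
    fig.savefig(artifacts["fig_compelled"], dpi=120)
    plt.close(fig)
    return artifacts


# ------------------------------------------------------------------ report


def make_report(bundle_dir: Union[str, Path]) -> str:
    """Human-readable summary rendered from a completed bundle directory."""
    bundle = Path(bundle_dir)
    required = ["metrics.csv", "classification.csv", "knee.json", "stats.json"]
    missing = [name for name in required if not (bundle / name).exists()]
    if missing:
        raise PipelineError(f"report: bundle incomplete, missing {missing}")
    classes = pd.read_csv(bundle / "classification.csv")
    knee = json.loads((bundle / "knee.json").read_text())
    stats_doc = json.loads((bundle / "stats.json").read_text())

    lines = ["# Star-maze analysis report", ""]
    lines.append("## Stabilization trial (knee)")
    for g, doc in sorted(knee.items()):
        lines.append(f"- {g}: knee at training trial {doc['knee']}")
    lines.append("")
    lines.append("## Strategy shares")
    for g, sub in classes.groupby("group"):
        shares = (sub["strategy"].value_counts(normalize=True) * 100).round(0)
        txt = ", ".join(f"{lab} {pct:.0f}%" for lab, pct in shares.items())
        lines.append(f"- {g} (n={len(sub)}): {txt}")
    lines.append("")
    if "stable_table" in stats_doc:
        lines.append("## Performance at the stable trial (median, IQR, Mann-Whitney p)")
        for row in stats_doc["stable_table"]:
            cells = [f"{k}={v:.3g}" if isinstance(v, float) else f"{k}={v}" for k, v in row.items()
                     if v is not None]
            lines.append("- " + ", ".join(cells))
        lines.append("")
    if "posthoc_power_d1_onetailed" in stats_doc:
        lines.append(
            f"Post-hoc power (d=1, one-tailed, alpha=0.05): "
            f"{stats_doc['posthoc_power_d1_onetailed']:.2f}"
        )
        lines.append("")
    return "\n".join(lines)
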