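"""Group learning curves and stabilization-trial ("knee") detection.

Across the 16 training trials of the free-navigation task, group medians of
four metrics (visited alleys, TPL, DE, RA) fall steeply and then flatten.
The stabilization trial is the bend of that curve.  The search is made
explicit here: the knee is the smallest candidate trial *k* such that, for
all four metrics, a Friedman test over trials k..16 is non-significant
(performance stable after the knee) while a paired Wilcoxon signed-rank
test between trials k−1 and k is significant (performance still changing
at the bend).

Conventions: Wilcoxon drops zero differences and uses the exact null
distribution for small samples without ties (falling back to the normal
approximation otherwise); participants with a missing value in any trial
involved in a test are dropped from that test (complete case per test).
For the last candidate (k = 15) only two trials remain after the knee, too
few for a Friedman test, so stability is assessed with a paired Wilcoxon
between trials 15 and 16.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats as st

from .maze import IDEAL_1_TO_3_M, Maze, ideal_path
from .stats import mann_whitney

__all__ = [
    "LEARNING_METRICS",
    "N_TRAINING_TRIALS",
    "LearningCurve",
    "KneeResult",
    "group_learning_curves",
    "training_matrix",
    "training_matrices",
    "detect_knee",
    "stable_performance_table",
]

#: The four metrics whose learning curves define the knee.
LEARNING_METRICS = ("visited_n", "tpl_m", "de_pct", "ra_deg")
N_TRAINING_TRIALS = 16


@dataclass
class LearningCurve:
    """Per-training-trial group median and IQR of one metric."""

    metric: str
    group: str
    trials: np.ndarray  # training trial numbers 1..16
    median: np.ndarray
    iqr: np.ndarray
    matrix: pd.DataFrame  # participants × training trials


def training_matrix(metrics_df: pd.DataFrame, group: str, metric: str) -> pd.DataFrame:
    """Participant × training-trial value matrix (NaN where a trial is missing)."""
    df = metrics_df[(metrics_df["group"] == group) & (metrics_df["trial_type"] == "training")]
    if df.empty:
        raise ValueError(f"no training trials for group {group!r}")
    mat = df.pivot_table(
        index="participant_id", columns="training_number", values=metric, aggfunc="first"
    )
    return mat.reindex(columns=range(1, N_TRAINING_TRIALS + 1))


def training_matrices(
    metrics_df: pd.DataFrame, group: str, metrics: Sequence[str] = LEARNING_METRICS
) -> Dict[str, pd.DataFrame]:
    return {m: training_matrix(metrics_df, group, m) for m in metrics}


def group_learning_curves(metrics_df: pd.DataFrame, group: str, metric: str) -> LearningCurve:
    """Median and IQR of ``metric`` per training trial across a group."""
    mat = training_matrix(metrics_df, group, metric)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        median = np.nanmedian(mat.to_numpy(), axis=0)
        q75 = np.nanpercentile(mat.to_numpy(), 75, axis=0)
        q25 = np.nanpercentile(mat.to_numpy(), 25, axis=0)
    return LearningCurve(
        metric=metric,
        group=group,
        trials=np.arange(1, N_TRAINING_TRIALS + 1),
        median=median,
        iqr=q75 - q25,
        matrix=mat,
    )


@dataclass
class KneeResult:
    """Detected stabilization trial with full diagnostics."""

    knee: Optional[int]
    friedman_p: Dict[str, float] = field(default_factory=dict)  # at the knee, per metric
    wilcoxon_p: Dict[str, float] = field(default_factory=dict)
    alpha_stable: float = 0.05
    alpha_change: float = 0.05
    candidates: pd.DataFrame = field(default_factory=pd.DataFrame)  # all evaluations


def _stability_p(data: np.ndarray) -> float:
    """Friedman p over the trials after the candidate knee (Wilcoxon for 2 columns)."""
    data = data[~np.isnan(data).any(axis=1)]
    if len(data) < 2:
        return np.nan
    if np.allclose(data, data[:, :1]):
        return 1.0  # identical repeated measures: perfectly stable
    if data.shape[1] == 2:
        return _paired_wilcoxon_p(data[:, 0], data[:, 1])
    stat, p = st.friedmanchisquare(*[data[:, j] for j in range(data.shape[1])])
    return float(p)


def _paired_wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask], b[mask]
    if len(a) < 2:
        return np.nan
    diff = a - b
    if np.allclose(diff, 0.0):
        return 1.0  # no change detectable
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = st.wilcoxon(a, b, zero_method="wilcox", method="auto")
    return float(res.pvalue)


def detect_knee(
    matrices: Mapping[str, pd.DataFrame],
    alpha_stable: float = 0.05,
    alpha_change: float = 0.05,
    candidates: Iterable[int] = range(2, N_TRAINING_TRIALS),
) -> KneeResult:
    """Smallest candidate trial that is stable after and different before.

    ``matrices`` maps metric name → participant × training-trial matrix.
    The knee is the smallest k with, for every metric, Friedman p over
    trials k..16 above ``alpha_stable`` AND paired Wilcoxon p between
    trials k−1 and k below ``alpha_change``; None when no candidate
    qualifies.
    """
    if not matrices:
        raise ValueError("at least one metric matrix is required")
    for name, mat in matrices.items():
        n = len(mat.dropna(how="all"))
        if n < 5:
            raise ValueError(
                f"metric {name!r}: {n} participants; at least 5 are needed for the paired tests"
            )

    rows = []
    knee: Optional[int] = None
    knee_f: Dict[str, float] = {}
    knee_w: Dict[str, float] = {}
    for k in candidates:
        ok = True
        f_ps: Dict[str, float] = {}
        w_ps: Dict[str, float] = {}
        for name, mat in matrices.items():
            arr = mat.to_numpy(dtype=float)
            f_p = _stability_p(arr[:, k - 1 : N_TRAINING_TRIALS])
            w_p = _paired_wilcoxon_p(arr[:, k - 2], arr[:, k - 1])
            f_ps[name] = f_p
            w_ps[name] = w_p
            if not (np.isfinite(f_p) and np.isfinite(w_p) and f_p > alpha_stable and w_p < alpha_change):
                ok = False
            rows.append({"candidate": k, "metric": name, "friedman_p": f_p, "wilcoxon_p": w_p})
        if ok and knee is None:
            knee, knee_f, knee_w = k, f_ps, w_ps
    return KneeResult(
        knee=knee,
        friedman_p=knee_f,
        wilcoxon_p=knee_w,
        alpha_stable=alpha_stable,
        alpha_change=alpha_change,
        candidates=pd.DataFrame(rows),
    )


#: Theoretical values of the stable-performance summary: a perfect run
#: visits 2 alleys, travels the ideal distance and has zero DE and RA.
def _theoretical_values(maze: Optional[Maze]) -> Dict[str, Optional[float]]:
    tpl = ideal_path(1, 3, maze).length if maze is not None else IDEAL_1_TO_3_M
    return {
        "visited_n": 2.0,
        "tpl_m": tpl,
        "de_pct": 0.0,
        "ra_deg": 0.0,
        "mean_speed_m_s": None,
        "time_s": None,
    }


def stable_performance_table(
    metrics_df: pd.DataFrame,
    knee_by_group: Mapping[str, int],
    maze: Optional[Maze] = None,
    groups: Tuple[str, str] = ("CP", "TD"),
) -> pd.DataFrame:
    """Per-metric median (IQR) at each group's knee trial, with Mann-Whitney p.

    Mirrors the published stable-trial summary: one row per variable
    (visited alleys, TPL, DE, RA, mean speed, time), the theoretical value
    of a perfect run, and the between-group comparison at each group's own
    stabilization trial.
    """
    th = _theoretical_values(maze)
    variables = ["visited_n", "tpl_m", "de_pct", "ra_deg", "mean_speed_m_s", "time_s"]
    df = metrics_df[metrics_df["trial_type"] == "training"]
    rows = []
    for var in variables:
        samples = {}
        for g in groups:
            knee = knee_by_group[g]
            vals = df[(df["group"] == g) & (df["training_number"] == knee)][var]
            samples[g] = vals.dropna().to_numpy(dtype=float)
        a, b = samples[groups[0]], samples[groups[1]]
        if len(a) and len(b):
            _, p = mann_whitney(a, b)
        else:
            p = np.nan
        row = {"variable": var, "th_value": th[var], "p_mann_whitney": p}
        for g in groups:
            vals = samples[g]
            if len(vals):
                row[f"{g}_median"] = float(np.median(vals))
                row[f"{g}_iqr"] = float(np.percentile(vals, 75) - np.percentile(vals, 25))
            else:
                row[f"{g}_median"] = row[f"{g}_iqr"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
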