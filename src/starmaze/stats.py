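"""Between-group statistics: demographics, correlations, power.

Pinned nonparametric conventions (the originals were run in a commercial
package whose exact tie handling is undocumented, so the conventions here
are fixed and covered by tests):

* Mann-Whitney U: exact p when there are no ties and min(n1, n2) ≤ 8,
  otherwise tie-corrected normal approximation without continuity
  correction; two-sided by default.
* Gender 2×2 table: Pearson chi-square without continuity correction
  (this reproduces the published p = 0.063; the Yates-corrected variant
  does not).
* Continuous variables: unpaired t-test when both groups pass a Lilliefors
  normality test at α = 0.05, Mann-Whitney otherwise.
* Spearman rank correlation for the learning-phase vs z-score analysis.
* Post-hoc power of the two-sample t-test via the noncentral t
  distribution; one-tailed by default (the published 0.82 for n = 13 vs 15
  at d = 1 is the one-tailed value).

No multiple-testing correction is applied anywhere; p-values are raw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "mann_whitney",
    "gender_chi_square",
    "lilliefors_normal",
    "compare_continuous",
    "compare_demographics",
    "learning_phase_correlations",
    "posthoc_power",
    "compare_navigation",
]


@dataclass
class GroupComparison:
    variable: str
    test: str  # mann_whitney | t_test | chi_square
    statistic: float
    p: float
    descriptives: Dict[str, str]
    normality: Optional[Dict[str, bool]] = None


@dataclass
class CorrelationResult:
    metric: str
    score: str
    rho: float
    p: float
    n: int


# ------------------------------------------------------------------ primitives


def mann_whitney(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> Tuple[float, float]:
    """Mann-Whitney U and p under the pinned convention (see module docstring)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (not has_ties and min(len(x), len(y)) <= 8) else "asymptotic"
    res = st.mannwhitneyu(x, y, alternative=alternative, method=method, use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def gender_chi_square(table: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Pearson chi-square (no continuity correction) of a 2×2 count table."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    chi2, p, _, _ = st.chi2_contingency(arr, correction=False)
    return float(chi2), float(p)


def lilliefors_normal(x: Sequence[float], alpha: float = 0.05) -> bool:
    """True when a Lilliefors test does not reject normality at ``alpha``."""
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        return False  # too small to assess; be conservative and use ranks
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = lilliefors(x, dist="norm")
    return bool(p > alpha)


def _median_iqr(x: np.ndarray) -> str:
    return f"{np.median(x):.3g} ({np.percentile(x, 75) - np.percentile(x, 25):.3g})"


def _mean_sd(x: np.ndarray) -> str:
    return f"{np.mean(x):.3g} ± {np.std(x, ddof=1):.3g}"


def compare_continuous(
    name: str, x: Sequence[float], y: Sequence[float], labels: Tuple[str, str] = ("CP", "TD")
) -> GroupComparison:
    """Normality-gated two-group comparison of a continuous variable."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    y = np.asarray(y, dtype=float)
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError(f"{name}: a group is empty")
    normal = {labels[0]: lilliefors_normal(x), labels[1]: lilliefors_normal(y)}
    if all(normal.values()):
        stat, p = st.ttest_ind(x, y, equal_var=True)
        return GroupComparison(
            name, "t_test", float(stat), float(p),
            {labels[0]: _mean_sd(x), labels[1]: _mean_sd(y)}, normal,
        )
    stat, p = mann_whitney(x, y)
    return GroupComparison(
        name, "mann_whitney", stat, p,
        {labels[0]: _median_iqr(x), labels[1]: _median_iqr(y)}, normal,
    )


# ------------------------------------------------------------------ study-level


def compare_demographics(
    participants_df: pd.DataFrame, groups: Tuple[str, str] = ("CP", "TD")
) -> List[GroupComparison]:
    """Gender, age and test z-score comparisons between the two groups.

    Expects one row per participant with columns ``group`` and any of
    ``sex`` (M/F), ``age_years``, ``raven_z``, ``corsi_z``,
    ``labyrinth_z``.  Continuous variables use the normality-gated rule;
    gender uses the uncorrected 2×2 Pearson chi-square.
    """
    for g in groups:
        if not (participants_df["group"] == g).any():
            raise ValueError(f"group {g!r} is empty")
    out: List[GroupComparison] = []
    if "sex" in participants_df.columns and participants_df["sex"].notna().any():
        table = []
        counts = {}
        for g in groups:
            sexes = participants_df.loc[participants_df["group"] == g, "sex"].dropna()
            m, f = int((sexes == "M").sum()), int((sexes == "F").sum())
            table.append([m, f])
            counts[g] = f"{m}/{f}"
        chi2, p = gender_chi_square(table)
        out.append(GroupComparison("gender_mf", "chi_square", chi2, p, counts))
    for var in ("age_years", "raven_z", "corsi_z", "labyrinth_z"):
        if var not in participants_df.columns:
            continue
        samples = [
            participants_df.loc[participants_df["group"] == g, var].dropna().to_numpy(dtype=float)
            for g in groups
        ]
        if any(len(s) == 0 for s in samples):
            continue
        out.append(compare_continuous(var, samples[0], samples[1], labels=groups))
    return out


def learning_phase_correlations(
    metrics_df: pd.DataFrame,
    participants_df: pd.DataFrame,
    knee_by_group: Mapping[str, int],
    metrics: Sequence[str] = ("visited_n", "tpl_m", "de_pct", "ra_deg"),
    scores: Sequence[str] = ("corsi_z", "labyrinth_z", "raven_z"),
) -> List[CorrelationResult]:
    """Spearman correlations between pre-knee medians and test z-scores.

    For each participant the median of each metric over the training trials
    *before* their group's stabilization trial (trials 1..knee−1) is
    computed; the medians are pooled across groups and correlated with each
    z-score (pairwise deletion).  Pairs with fewer than 3 complete
    observations yield NaN.
    """
    df = metrics_df[metrics_df["trial_type"] == "training"]
    rows = []
    for pid, sub in df.groupby("participant_id"):
        group = sub["group"].iloc[0]
        knee = knee_by_group[group]
        pre = sub[sub["training_number"] < knee]
        row = {"participant_id": pid}
        for m in metrics:
            vals = pre[m].dropna()
            row[m] = float(vals.median()) if len(vals) else np.nan
        rows.append(row)
    medians = pd.DataFrame(rows).merge(
        participants_df[["participant_id", *[s for s in scores if s in participants_df.columns]]],
        on="participant_id",
        how="left",
    )
    out: List[CorrelationResult] = []
    for m in metrics:
        for s in scores:
            if s not in medians.columns:
                out.append(CorrelationResult(m, s, np.nan, np.nan, 0))
                continue
            pair = medians[[m, s]].dropna()
            if len(pair) < 3:
                out.append(CorrelationResult(m, s, np.nan, np.nan, len(pair)))
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # constant columns yield NaN rho
                rho, p = st.spearmanr(pair[m], pair[s])
            out.append(CorrelationResult(m, s, float(rho), float(p), len(pair)))
    return out


def posthoc_power(n1: int, n2: int, d: float, alpha: float = 0.05, tails: int = 1) -> float:
    """Power of the two-sample t-test at effect size ``d`` (Cohen).

    Uses the noncentral t distribution with noncentrality
    d·sqrt(n1·n2/(n1+n2)) and n1+n2−2 degrees of freedom.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if n1 < 2 or n2 < 2:
        raise ValueError("both sample sizes must be at least 2")
    if d < 0:
        raise ValueError("effect size d must be non-negative")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    df = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    if tails == 1:
        crit = st.t.ppf(1.0 - alpha, df)
        return float(st.nct.sf(crit, df, ncp))
    crit = st.t.ppf(1.0 - alpha / 2.0, df)
    return float(st.nct.sf(crit, df, ncp) + st.nct.cdf(-crit, df, ncp))


def compare_navigation(
    metrics_df: pd.DataFrame,
    knee_by_group: Mapping[str, int],
    compelled_df: Optional[pd.DataFrame] = None,
    groups: Tuple[str, str] = ("CP", "TD"),
) -> List[GroupComparison]:
    """Mann-Whitney comparisons of navigation performance between groups.

    Stable-trial metrics are compared at each group's own knee trial;
    when ``compelled_df`` (per participant ``compelled_as_pct`` /
    ``compelled_es_pct`` + ``group``) is given, the compelled success rates
    are compared as well.
    """
    out: List[GroupComparison] = []
    train = metrics_df[metrics_df["trial_type"] == "training"]
    for var in ("visited_n", "tpl_m", "de_pct", "ra_deg", "mean_speed_m_s", "time_s"):
        if var not in train.columns:
            continue
        samples = []
        for g in groups:
            knee = knee_by_group[g]
            vals = train[(train["group"] == g) & (train["training_number"] == knee)][var]
            samples.append(vals.dropna().to_numpy(dtype=float))
        if any(len(s) == 0 for s in samples):
            continue
        stat, p = mann_whitney(samples[0], samples[1])
        out.append(
            GroupComparison(
                f"{var}@stable", "mann_whitney", stat, p,
                {groups[0]: _median_iqr(samples[0]), groups[1]: _median_iqr(samples[1])},
            )
        )
    if compelled_df is not None:
        for var in ("compelled_as_pct", "compelled_es_pct"):
            if var not in compelled_df.columns:
                continue
            samples = [
                compelled_df.loc[compelled_df["group"] == g, var].dropna().to_numpy(dtype=float)
                for g in groups
            ]
            if any(len(s) == 0 for s in samples):
                continue
            stat, p = mann_whitney(samples[0], samples[1])
            out.append(
                GroupComparison(
                    var, "mann_whitney", stat, p,
                    {groups[0]: _median_iqr(samples[0]), groups[1]: _median_iqr(samples[1])},
                )
            )
    return out
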