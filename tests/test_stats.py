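"""Group statistics against enumeration and closed-form oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

import starmaze as sm
from starmaze import stats


def mann_whitney_enumeration_oracle(x, y):
    """Exact two-sided p by enumerating every group assignment of the pooled sample."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)
    obs_u = _u_statistic(x, y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(_u_statistic(a, b))
    us = np.array(us)
    p = 2 * min((us <= obs_u).mean(), (us >= obs_u).mean())
    return min(p, 1.0)


def _u_statistic(a, b):
    return sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b)


class TestMannWhitney:
    def test_matches_enumeration_on_all_small_shapes(self):
        rng = np.random.default_rng(0)
        for n1, n2 in [(1, 9), (2, 5), (3, 3), (4, 6), (5, 5), (2, 8)]:
            for _ in range(3):
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                _, p = sm.mann_whitney(x, y)
                assert p == pytest.approx(mann_whitney_enumeration_oracle(x, y), abs=1e-12)

    def test_separated_samples_one_sided_exact(self):
        # all 20 assignments of {1,2,3} vs {11,12,13}: exactly one is as extreme
        import scipy.stats as st

        res = st.mannwhitneyu([1, 2, 3], [11, 12, 13], alternative="less", method="exact")
        assert res.pvalue == pytest.approx(1 / 20)

    def test_identical_samples_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0]
        _, p = sm.mann_whitney(x, x)
        assert p == pytest.approx(1.0)

    def test_null_rejection_rate_about_five_percent(self):
        rng = np.random.default_rng(1)
        n_rep = 400
        rej = 0
        for _ in range(n_rep):
            x = rng.lognormal(0, 0.5, 15)
            y = rng.lognormal(0, 0.5, 13)
            _, p = sm.mann_whitney(x, y)
            rej += p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rej / n_rep - 0.05) < 3 * se


class TestChiSquare:
    def test_study_gender_table(self):
        chi2, p = sm.gender_chi_square([[11, 4], [5, 8]])
        assert round(p, 3) == 0.063

    def test_statistic_matches_hand_formula(self):
        table = np.array([[11, 4], [5, 8]], dtype=float)
        n = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / n
        oracle = ((table - expected) ** 2 / expected).sum()
        chi2, _ = sm.gender_chi_square(table)
        assert chi2 == pytest.approx(oracle)
        assert chi2 == pytest.approx(3.458, abs=2e-3)

    def test_balanced_table_p_one(self):
        _, p = sm.gender_chi_square([[10, 10], [10, 10]])
        assert p == pytest.approx(1.0)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            sm.gender_chi_square([[1, 2, 3], [4, 5, 6]])


class TestPower:
    def test_study_configuration(self):
        assert sm.posthoc_power(13, 15, 1.0, 0.05, tails=1) == pytest.approx(0.82, abs=0.01)

    def test_zero_effect_gives_alpha(self):
        assert sm.posthoc_power(10, 10, 0.0, 0.05, tails=1) == pytest.approx(0.05, abs=1e-9)

    def test_huge_samples_saturate(self):
        assert sm.posthoc_power(10_000, 10_000, 1.0, 0.05, tails=1) > 0.999

    def test_monotone_in_effect_n_and_alpha(self):
        grid = [sm.posthoc_power(13, 15, d, 0.05) for d in (0.2, 0.5, 1.0, 1.5)]
        assert grid == sorted(grid)
        assert sm.posthoc_power(20, 20, 0.8) > sm.posthoc_power(10, 10, 0.8)
        assert sm.posthoc_power(13, 15, 1.0, alpha=0.10) > sm.posthoc_power(13, 15, 1.0, alpha=0.01)

    def test_matches_statsmodels(self):
        from statsmodels.stats.power import TTestIndPower

        ref = TTestIndPower().power(1.0, nobs1=13, ratio=15 / 13, alpha=0.05, alternative="larger")
        assert sm.posthoc_power(13, 15, 1.0, 0.05, tails=1) == pytest.approx(ref, abs=1e-9)

    @pytest.mark.parametrize("bad", [{"alpha": 0.0}, {"alpha": 1.5}, {"d": -1.0}, {"n1": 1}])
    def test_invalid_inputs_rejected(self, bad):
        kwargs = {"n1": 13, "n2": 15, "d": 1.0, "alpha": 0.05}
        kwargs.update(bad)
        with pytest.raises(ValueError):
            sm.posthoc_power(**kwargs)


class TestNormalityGate:
    def test_normal_data_uses_t_test(self):
        rng = np.random.default_rng(2)
        cmp = stats.compare_continuous("age", rng.normal(10, 2, 15), rng.normal(10, 2, 13))
        assert cmp.test == "t_test"

    def test_skewed_data_uses_mann_whitney(self):
        rng = np.random.default_rng(3)
        cmp = stats.compare_continuous("z", rng.lognormal(0, 1.5, 20) ** 2, rng.normal(0, 1, 20))
        assert cmp.test == "mann_whitney"


class TestDemographics:
    def _participants(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(15):
            rows.append({"participant_id": f"CP{i}", "group": "CP", "sex": "M" if i < 11 else "F",
                         "age_years": rng.normal(10.4, 2.2), "raven_z": rng.normal(0, 1)})
        for i in range(13):
            rows.append({"participant_id": f"TD{i}", "group": "TD", "sex": "M" if i < 5 else "F",
                         "age_years": rng.normal(10.4, 2.3), "raven_z": rng.normal(1, 1)})
        return pd.DataFrame(rows)

    def test_gender_row_reproduces_study_table(self):
        out = sm.compare_demographics(self._participants())
        gender = next(c for c in out if c.variable == "gender_mf")
        assert gender.test == "chi_square"
        assert round(gender.p, 3) == 0.063
        assert gender.descriptives == {"CP": "11/4", "TD": "5/8"}

    def test_empty_group_rejected(self):
        df = self._participants()
        with pytest.raises(ValueError):
            sm.compare_demographics(df[df["group"] == "CP"])


class TestCorrelations:
    def _frames(self, link):
        rng = np.random.default_rng(6)
        rows, parts = [], []
        for i in range(12):
            level = rng.uniform(0, 5)
            parts.append({"participant_id": f"P{i}", "group": "TD", "corsi_z": link(level),
                          "labyrinth_z": rng.normal(), "raven_z": rng.normal()})
            for t in range(1, 17):
                rows.append({"participant_id": f"P{i}", "group": "TD", "trial_type": "training",
                             "training_number": t, "visited_n": 2, "tpl_m": 246 + level,
                             "de_pct": level, "ra_deg": 10 * level})
        return pd.DataFrame(rows), pd.DataFrame(parts)

    def test_perfect_monotone_links(self):
        metrics_df, parts = self._frames(lambda lv: lv)
        out = sm.learning_phase_correlations(metrics_df, parts, {"TD": 5})
        by = {(c.metric, c.score): c for c in out}
        assert by[("tpl_m", "corsi_z")].rho == pytest.approx(1.0)
        metrics_df, parts = self._frames(lambda lv: -lv)
        out = sm.learning_phase_correlations(metrics_df, parts, {"TD": 5})
        by = {(c.metric, c.score): c for c in out}
        assert by[("de_pct", "corsi_z")].rho == pytest.approx(-1.0)

    def test_twelve_pairs_reported(self):
        metrics_df, parts = self._frames(lambda lv: lv)
        out = sm.learning_phase_correlations(metrics_df, parts, {"TD": 5})
        assert len(out) == 12

    def test_planted_negative_link_recovered_from_simulation(self):
        # corsi_z is generated to increase with learning aptitude, so slower
        # noisier learners travel farther pre-knee: rho(TPL, corsi) < 0
        cfg = sm.CohortConfig(
            groups={"TD": sm.GroupConfig(n=10, mixture={"egocentric": 1.0})}, seed=9
        )
        cohort, _ = sm.simulate_cohort(cfg)
        from starmaze.pipeline import cohort_metrics_frame, participants_frame

        df = cohort_metrics_frame(cohort, sm.build_maze(), sm.default_protocol(0))
        out = sm.learning_phase_correlations(df, participants_frame(cohort), {"TD": 6})
        by = {(c.metric, c.score): c for c in out}
        assert by[("tpl_m", "corsi_z")].rho < 0

    def test_spearman_invariant_under_monotone_transform(self):
        metrics_df, parts = self._frames(lambda lv: lv)
        out1 = sm.learning_phase_correlations(metrics_df, parts, {"TD": 5})
        parts2 = parts.copy()
        parts2["corsi_z"] = np.exp(parts2["corsi_z"])
        out2 = sm.learning_phase_correlations(metrics_df, parts2, {"TD": 5})
        by1 = {(c.metric, c.score): c.rho for c in out1}
        by2 = {(c.metric, c.score): c.rho for c in out2}
        assert by1[("ra_deg", "corsi_z")] == pytest.approx(by2[("ra_deg", "corsi_z")])
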