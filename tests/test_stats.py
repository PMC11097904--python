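import numpy as np
import pandas as pd
import pytest

import rotovis as rv
from rotovis import observer as obs, psychfit as pf, stats as st
from rotovis.design import TrialPlan
from tests.conftest import SEED


def toy_table(values: dict, participants=None) -> pd.DataFrame:
    """Long threshold table from {(participant, direction, congruence): value}."""
    rot_for = {
        ("left", "congruent"): "left",
        ("left", "incongruent"): "right",
        ("left", "stationary"): "stationary",
        ("right", "congruent"): "right",
        ("right", "incongruent"): "left",
        ("right", "stationary"): "stationary",
    }
    rows = []
    for (p, d, c), v in values.items():
        rows.append(
            dict(participant=p, stim_direction=d, head_rotation=rot_for[(d, c)],
                 congruence=c, threshold=v, excluded=False)
        )
    return pd.DataFrame(rows)


def grid_table(n_participants, fn):
    vals = {}
    for p in range(n_participants):
        for d in ("left", "right"):
            for c in ("congruent", "incongruent", "stationary"):
                vals[(f"p{p}", d, c)] = fn(p, d, c)
    return toy_table(vals)


def anova_by_hand(table):
    """From-scratch balanced two-way within-subject ANOVA sums of squares."""
    wide = table.pivot_table(
        index="participant", columns=["stim_direction", "congruence"], values="threshold"
    )
    y = wide.to_numpy()  # n x 6, columns (d, c)
    n = y.shape[0]
    dirs = wide.columns.get_level_values(0).to_numpy()
    conds = wide.columns.get_level_values(1).to_numpy()
    grand = y.mean()
    subj_m = y.mean(axis=1)
    out = {}
    # direction
    levels_d = np.unique(dirs)
    md = np.array([y[:, dirs == d].mean() for d in levels_d])
    ss_d = n * 3 * ((md - grand) ** 2).sum()
    cell_sd = np.stack([y[:, dirs == d].mean(axis=1) for d in levels_d], axis=1)
    ss_sd = 3 * ((cell_sd - subj_m[:, None] - md[None, :] + grand) ** 2).sum()
    out["direction"] = (ss_d / (len(levels_d) - 1)) / (ss_sd / ((len(levels_d) - 1) * (n - 1)))
    # congruence
    levels_c = np.unique(conds)
    mc = np.array([y[:, conds == c].mean() for c in levels_c])
    ss_c = n * 2 * ((mc - grand) ** 2).sum()
    cell_sc = np.stack([y[:, conds == c].mean(axis=1) for c in levels_c], axis=1)
    ss_sc = 2 * ((cell_sc - subj_m[:, None] - mc[None, :] + grand) ** 2).sum()
    out["congruence"] = (ss_c / (len(levels_c) - 1)) / (ss_sc / ((len(levels_c) - 1) * (n - 1)))
    # interaction
    mdc = np.zeros((len(levels_d), len(levels_c)))
    for i, d in enumerate(levels_d):
        for j, c in enumerate(levels_c):
            mdc[i, j] = y[:, (dirs == d) & (conds == c)].mean()
    ss_i = n * ((mdc - md[:, None] - mc[None, :] + grand) ** 2).sum()
    resid = 0.0
    for i, d in enumerate(levels_d):
        for j, c in enumerate(levels_c):
            cell = y[:, (dirs == d) & (conds == c)].ravel()
            pred = subj_m + mdc[i, j] - grand + (cell_sd[:, i] - subj_m - md[i] + grand) + (
                cell_sc[:, j] - subj_m - mc[j] + grand
            )
            resid += ((cell - pred) ** 2).sum()
    df_i = (len(levels_d) - 1) * (len(levels_c) - 1)
    out["interaction"] = (ss_i / df_i) / (resid / (df_i * (n - 1)))
    return out


class TestRmAnova:
    def test_identical_thresholds_give_zero_F(self):
        table = grid_table(4, lambda p, d, c: 0.3)
        for res in st.rm_anova_2x3(table):
            assert res.F == 0.0 and res.p == 1.0

    def test_agrees_with_hand_computed_sums_of_squares(self):
        table = grid_table(4, lambda p, d, c: 0.0)
        rng = np.random.default_rng(SEED)
        table["threshold"] = (
            0.3
            + 0.1 * (table["congruence"] == "incongruent")
            + 0.02 * (table["stim_direction"] == "left")
            + rng.normal(0, 0.05, len(table))
        )
        expected = anova_by_hand(table)
        got = {r.effect: r.F for r in st.rm_anova_2x3(table)}
        for effect in ("direction", "congruence", "interaction"):
            assert got[effect] == pytest.approx(expected[effect], abs=1e-8)

    def test_df_rule_with_8_complete_participants(self):
        rng = np.random.default_rng(SEED)
        table = grid_table(8, lambda p, d, c: 0.3)
        table["threshold"] += rng.normal(0, 0.03, len(table))
        res = {r.effect: r for r in st.rm_anova_2x3(table)}
        assert (res["congruence"].df_num, res["congruence"].df_den) == (2, 14)
        assert (res["direction"].df_num, res["direction"].df_den) == (1, 7)

    def test_incomplete_participants_are_dropped(self):
        rng = np.random.default_rng(SEED)
        table = grid_table(5, lambda p, d, c: 0.3)
        table["threshold"] += rng.normal(0, 0.03, len(table))
        table.loc[
            (table["participant"] == "p0") & (table["congruence"] == "congruent"),
            "excluded",
        ] = True
        res = st.rm_anova_2x3(table)
        assert res[0].df_den == 3  # 4 complete participants -> df 3 for direction

    def test_too_few_complete(self):
        table = grid_table(2, lambda p, d, c: 0.3)
        with pytest.raises(ValueError):
            st.rm_anova_2x3(table)


class TestPosthoc:
    def test_identical_groups(self):
        table = grid_table(4, lambda p, d, c: 0.3)
        for res in st.posthoc_bonferroni(table):
            assert res.t == 0.0 and res.cohen_d == 0.0 and res.p_bonferroni == 1.0

    def test_matches_hand_computation(self):
        # 3 participants, constant within participant-condition
        base = {"p0": 0.2, "p1": 0.3, "p2": 0.4}
        bump = {"p0": 0.10, "p1": 0.12, "p2": 0.20}
        table = grid_table(
            3, lambda p, d, c: base[f"p{p}"] + (bump[f"p{p}"] if c == "incongruent" else 0.0)
        )
        res = {r.contrast: r for r in st.posthoc_bonferroni(table)}
        diffs = np.array([0.10, 0.12, 0.20])  # incongruent - stationary per participant
        t_hand = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(3))
        d_hand = diffs.mean() / diffs.std(ddof=1)
        r = res["incongruent - stationary"]
        assert r.t == pytest.approx(t_hand, abs=1e-10)
        assert r.cohen_d == pytest.approx(d_hand, abs=1e-10)
        assert r.df == 2

    def test_sign_convention(self):
        table = grid_table(
            4, lambda p, d, c: 0.3 + 0.1 * (1 + 0.2 * p) * (c == "incongruent")
        )
        res = {r.contrast: r for r in st.posthoc_bonferroni(table)}
        assert res["incongruent - stationary"].t > 0
        assert res["congruent - incongruent"].t < 0

    def test_bonferroni_capped_at_one(self):
        rng = np.random.default_rng(SEED)
        table = grid_table(6, lambda p, d, c: 0.3)
        table["threshold"] += rng.normal(0, 0.05, len(table))
        assert all(r.p_bonferroni <= 1.0 for r in st.posthoc_bonferroni(table))


class TestLme:
    def test_lrt_identity_from_stored_logliks(self, exp1_threshold_table):
        lme = st.lme_stepwise(exp1_threshold_table)
        for i, step in enumerate(lme.steps):
            chi_recomputed = max(0.0, 2 * (lme.logliks[i + 1] - lme.logliks[i]))
            assert step.chi_sq == pytest.approx(chi_recomputed, abs=1e-12)

    def test_congruence_only_pattern_on_biased_cohort(self, exp1_threshold_table):
        lme = st.lme_stepwise(exp1_threshold_table)
        assert lme.steps[0].p < 0.05  # congruence improves the null model
        assert lme.steps[1].p > 0.05  # direction does not
        assert lme.steps[2].p > 0.05  # interaction does not
        assert "congruence" in lme.winning_formula and "stim_direction" not in lme.winning_formula
        names = [c.name for c in lme.coefficients]
        assert "incongruent - congruent" in names
        inc = next(c for c in lme.coefficients if c.name == "congruence[incongruent]")
        assert inc.beta > 0 and inc.ci_low < inc.beta < inc.ci_high

    def test_null_data_keeps_random_only_model(self):
        rng = np.random.default_rng(SEED)
        table = grid_table(10, lambda p, d, c: 0.3)
        table["threshold"] += rng.normal(0, 0.02, len(table))
        lme = st.lme_stepwise(table)
        assert lme.winning_formula == "threshold ~ 1"

    def test_too_few_participants(self):
        table = grid_table(2, lambda p, d, c: 0.3)
        with pytest.raises(ValueError):
            st.lme_stepwise(table)


def _make_traj(participant, condition, plateau, rng, rotation_dir="right"):
    stim_dir = "left"
    rot = condition if condition == "stationary" else rotation_dir
    plan = TrialPlan(
        experiment="exp1", block=1, trial_index=0,
        stim_direction=stim_dir, head_rotation=rot,
        congruence=rv.classify_congruence(stim_dir, rot), hemifield="n/a",
    )
    params = obs.ObserverParams(
        mu_by_condition={"stationary": 0.3, "congruent": 0.3, "incongruent": 0.3},
        speed_mean_deg_s=plateau, speed_sd_deg_s=0.5,
    )
    traj = obs.generate_head_trajectory(plan, params, rng)
    import dataclasses
    return dataclasses.replace(traj, participant=participant)


class TestHeadSpeed:
    def test_whole_rotation_mean_below_plateau(self):
        rng = np.random.default_rng(SEED)
        trajs = [_make_traj("p0", "right", 38.0, rng) for _ in range(10)]
        summary = st.summarize_head_speed(trajs)
        assert (summary.per_participant["mean_speed"] < 38.0).all()
        assert (summary.per_participant["mean_speed"] > 10.0).all()

    def test_stationary_trace_near_zero(self):
        rng = np.random.default_rng(SEED)
        trajs = [_make_traj("p0", "right", 38.0, rng), _make_traj("p0", "stationary", 38.0, rng)]
        summary = st.summarize_head_speed(trajs)
        assert summary.flagged == []

    def test_noncompliant_participant_flagged(self):
        rng = np.random.default_rng(SEED)
        trajs = [_make_traj("p0", "right", 38.0, rng) for _ in range(4)]
        # p1 barely turns the head on rotation trials
        trajs += [_make_traj("p1", "right", 2.0, rng) for _ in range(4)]
        summary = st.summarize_head_speed(trajs)
        assert summary.flagged == ["p1"]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            st.summarize_head_speed([])


class TestSpeedThresholdRegression:
    @staticmethod
    def _summary(speeds: dict) -> st.SpeedSummary:
        df = pd.DataFrame(
            [{"participant": p, "direction": "right", "mean_speed": v, "mean_within_sd": 1.0}
             for p, v in speeds.items()]
        )
        return st.SpeedSummary(per_participant=df, flagged=[], cohort_variability=1.0)

    @staticmethod
    def _table(thresholds: dict) -> pd.DataFrame:
        rows = []
        for p, v in thresholds.items():
            for d in ("left", "right"):
                rows.append(dict(participant=p, stim_direction=d, head_rotation="right",
                                 congruence=rv.classify_congruence(d, "right"),
                                 threshold=v, excluded=False))
        return pd.DataFrame(rows)

    def test_perfectly_collinear_gives_unit_r2(self):
        speeds = {f"p{i}": 30.0 + i for i in range(5)}
        thresholds = {p: 0.1 + 0.01 * s for p, s in speeds.items()}
        res = st.speed_threshold_regression(self._summary(speeds), self._table(thresholds), "right")
        assert res["adj_r2"] == pytest.approx(1.0, abs=1e-10)

    def test_df_rule(self):
        rng = np.random.default_rng(SEED)
        speeds = {f"p{i}": 30.0 + rng.normal(0, 3) for i in range(18)}
        thresholds = {p: 0.3 + rng.normal(0, 0.05) for p in speeds}
        res = st.speed_threshold_regression(self._summary(speeds), self._table(thresholds), "right")
        assert (res["df_num"], res["df_den"]) == (1, 16)

    def test_null_relationship_p_uniform(self):
        rng = np.random.default_rng(SEED)
        ps = []
        for _ in range(200):
            speeds = {f"p{i}": 30.0 + rng.normal(0, 3) for i in range(12)}
            thresholds = {p: 0.3 + rng.normal(0, 0.05) for p in speeds}
            res = st.speed_threshold_regression(self._summary(speeds), self._table(thresholds), "right")
            ps.append(res["p"])
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01
        assert abs(np.mean([st_ for st_ in ps]) - 0.5) < 0.1

    def test_constant_speed_errors(self):
        speeds = {f"p{i}": 30.0 for i in range(5)}
        thresholds = {p: 0.3 for p in speeds}
        with pytest.raises(ValueError):
            st.speed_threshold_regression(self._summary(speeds), self._table(thresholds), "right")
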