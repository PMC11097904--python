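"""Group-level inference on threshold tables and head kinematics.

Covers the repeated-measures 2 (stimulus direction) x 3 (rotation
congruence) ANOVA with Bonferroni-corrected paired post-hocs, the stepwise
nested mixed-model comparison by likelihood-ratio tests, and the head-speed
summaries and speed-threshold regressions.

The ANOVA uses listwise deletion (participants with all six cells), while
the mixed models use every available cell -- the two analyses intentionally
run on different effective samples, as their degrees of freedom make
explicit in the output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.formula.api as smf
from scipy import stats as sps

from .observer import HeadTrajectory

__all__ = [
    "AnovaResult",
    "PosthocResult",
    "LmeStep",
    "LmeCoefficient",
    "LmeComparison",
    "SpeedSummary",
    "rm_anova_2x3",
    "posthoc_bonferroni",
    "lme_stepwise",
    "summarize_head_speed",
    "speed_threshold_regression",
]


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class PosthocResult:
    contrast: str
    t: float
    df: int
    p_bonferroni: float
    cohen_d: float


@dataclass(frozen=True)
class LmeStep:
    comparison: str
    chi_sq: float
    df: int
    p: float


@dataclass(frozen=True)
class LmeCoefficient:
    name: str
    beta: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p: float


@dataclass
class LmeComparison:
    formulas: List[str]
    logliks: List[float]
    steps: List[LmeStep]
    winning_formula: str
    coefficients: List[LmeCoefficient]
    singular: bool


def _complete_cases(table: pd.DataFrame) -> pd.DataFrame:
    kept = table.loc[~table["excluded"]].copy()
    counts = kept.groupby("participant")["threshold"].count()
    complete = counts.index[counts == 6]
    return kept.loc[kept["participant"].isin(complete)]


def rm_anova_2x3(threshold_table: pd.DataFrame) -> List[AnovaResult]:
    """Two-factor within-subject ANOVA on thresholds.

    Factors: stimulus direction (left/right) and rotation congruence
    (congruent/incongruent/stationary).  Participants missing any of the
    six cells are dropped (listwise deletion).  Partial eta squared is
    SS_effect / (SS_effect + SS_error), recovered from F and the dfs.
    No sphericity correction is applied; uncorrected p-values are reported.
    """
    data = _complete_cases(threshold_table)
    n = data["participant"].nunique()
    if n < 3:
        raise ValueError(f"need at least 3 complete participants, got {n}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.rm_anova(
            data=data,
            dv="threshold",
            within=["stim_direction", "congruence"],
            subject="participant",
            detailed=True,
        )
    name_map = {
        "stim_direction": "direction",
        "congruence": "congruence",
        "stim_direction * congruence": "interaction",
    }
    results = []
    for _, row in aov.iterrows():
        f, d1, d2 = float(row["F"]), int(row["ddof1"]), int(row["ddof2"])
        p = float(row["p_unc"])
        if not np.isfinite(f):  # zero effect and zero error variance
            f, p = 0.0, 1.0
        results.append(
            AnovaResult(
                effect=name_map[row["Source"]],
                F=f,
                df_num=d1,
                df_den=d2,
                p=p,
                partial_eta_sq=f * d1 / (f * d1 + d2),
            )
        )
    return results


def posthoc_bonferroni(threshold_table: pd.DataFrame) -> List[PosthocResult]:
    """Paired t-tests between congruence levels on direction-collapsed
    thresholds, Bonferroni-corrected for the three pairwise contrasts.
    Cohen's d is the paired (difference-score) d: mean difference divided
    by the SD of the paired differences."""
    data = _complete_cases(threshold_table)
    if data["participant"].nunique() < 3:
        raise ValueError("need at least 3 complete participants")
    wide = (
        data.groupby(["participant", "congruence"])["threshold"]
        .mean()
        .unstack("congruence")
    )
    levels = ["congruent", "incongruent", "stationary"]
    results = []
    for a, b in combinations(levels, 2):
        diff = wide[a] - wide[b]
        n = len(diff)
        sd = diff.std(ddof=1)
        if sd == 0:
            t, p, d = 0.0, 1.0, 0.0
        else:
            t, p = sps.ttest_rel(wide[a], wide[b])
            d = float(diff.mean() / sd)
        results.append(
            PosthocResult(
                contrast=f"{a} - {b}",
                t=float(t),
                df=n - 1,
                p_bonferroni=float(min(1.0, p * 3)),
                cohen_d=d,
            )
        )
    return results


_LME_FORMULAS = [
    "threshold ~ 1",
    "threshold ~ C(congruence, Treatment('stationary'))",
    "threshold ~ C(congruence, Treatment('stationary')) + C(stim_direction)",
    "threshold ~ C(congruence, Treatment('stationary')) * C(stim_direction)",
]
_LME_LABELS = ["random-only", "+ congruence", "+ direction", "+ interaction"]


def lme_stepwise(threshold_table: pd.DataFrame, alpha: float = 0.05) -> LmeComparison:
    """Stepwise mixed-model comparison with random intercepts per participant.

    Fits, by maximum likelihood (not REML), the nested sequence
    intercept-only, + congruence, + stimulus direction, + their
    interaction, all with ``(1 | participant)``; compares adjacent models
    by likelihood-ratio tests.  The winning model is the last one in the
    sequence that significantly improved on its predecessor; its
    treatment-coded coefficients (reference: stationary) are reported with
    normal-based 95% CIs and t statistics on residual df, plus the
    congruent-vs-incongruent contrast.  Excluded cells are simply absent
    (all available cells are used; no listwise deletion).
    """
    data = threshold_table.loc[~threshold_table["excluded"]].copy()
    if data["participant"].nunique() < 3:
        raise ValueError("need at least 3 participants")
    fits = []
    singular = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for f in _LME_FORMULAS:
            m = smf.mixedlm(f, data, groups=data["participant"]).fit(reml=False)
            if not getattr(m, "converged", True):
                singular = True
            fits.append(m)

    steps = []
    winning_idx = 0
    for i in range(1, len(fits)):
        chi = max(0.0, 2 * (fits[i].llf - fits[i - 1].llf))
        df = int(fits[i].df_modelwc - fits[i - 1].df_modelwc)
        p = float(sps.chi2.sf(chi, df)) if df > 0 else 1.0
        steps.append(
            LmeStep(comparison=f"{_LME_LABELS[i]} vs {_LME_LABELS[i - 1]}", chi_sq=chi, df=df, p=p)
        )
        if p < alpha and winning_idx == i - 1:
            winning_idx = i

    win = fits[winning_idx]
    k_fe = len(win.fe_params)
    df_resid = int(win.nobs - k_fe)
    coefs = []
    for name in win.fe_params.index:
        beta = float(win.fe_params[name])
        se = float(win.bse_fe[name])
        t = beta / se if se > 0 else 0.0
        coefs.append(
            LmeCoefficient(
                name=_pretty_term(name),
                beta=beta,
                ci_low=beta - 1.96 * se,
                ci_high=beta + 1.96 * se,
                t=t,
                df=df_resid,
                p=float(2 * sps.t.sf(abs(t), df_resid)),
            )
        )
    contrast = _congruent_vs_incongruent(win, df_resid)
    if contrast is not None:
        coefs.append(contrast)
    return LmeComparison(
        formulas=list(_LME_FORMULAS),
        logliks=[float(m.llf) for m in fits],
        steps=steps,
        winning_formula=_LME_FORMULAS[winning_idx],
        coefficients=coefs,
        singular=singular,
    )


def _pretty_term(name: str) -> str:
    return (
        name.replace("C(congruence, Treatment('stationary'))[T.", "congruence[")
        .replace("C(stim_direction)[T.", "direction[")
    )


def _congruent_vs_incongruent(model, df_resid: int) -> Optional[LmeCoefficient]:
    idx = list(model.fe_params.index)
    cong = next((i for i, s in enumerate(idx) if "T.congruent]" in s and ":" not in s), None)
    inc = next((i for i, s in enumerate(idx) if "T.incongruent]" in s and ":" not in s), None)
    if cong is None or inc is None:
        return None
    L = np.zeros(len(model.params))
    L[inc], L[cong] = 1.0, -1.0
    beta = float(L[: len(idx)] @ model.fe_params.values)
    cov = np.asarray(model.cov_params())[: len(idx), : len(idx)]
    se = float(np.sqrt(L[: len(idx)] @ cov @ L[: len(idx)]))
    t = beta / se if se > 0 else 0.0
    return LmeCoefficient(
        name="incongruent - congruent",
        beta=beta,
        ci_low=beta - 1.96 * se,
        ci_high=beta + 1.96 * se,
        t=t,
        df=df_resid,
        p=float(2 * sps.t.sf(abs(t), df_resid)),
    )


@dataclass
class SpeedSummary:
    per_participant: pd.DataFrame  # participant, direction, mean_speed, mean_within_sd
    flagged: List[str]
    cohort_variability: float  # mean of per-participant within-trial speed SDs


def summarize_head_speed(
    trajectories: Sequence[HeadTrajectory],
    plateau_flag_deg_s: float = 10.0,
) -> SpeedSummary:
    """Per-participant head-speed statistics.

    For rotation trials, per-trial mean speed and within-trial SD are
    computed over the whole rotation (from guide arrival to stimulus
    offset, so the acceleration ramp dilutes the mean below the plateau).
    Participants whose mean speed in the stimulus window is below
    ``plateau_flag_deg_s`` on rotation trials, or above it while
    nominally stationary, are flagged as non-compliant.
    """
    if not trajectories:
        raise ValueError("no trajectories supplied")
    rows = []
    for traj in trajectories:
        if traj.time_s.size < 2:
            raise ValueError("trajectory too short")
        speed = traj.speed_deg_s()
        tmid = 0.5 * (traj.time_s[:-1] + traj.time_s[1:])
        rot_window = (tmid >= 1.0) & (tmid <= traj.stim_offset_s)
        stim_window = (tmid >= traj.stim_onset_s) & (tmid <= traj.stim_offset_s)
        rows.append(
            {
                "participant": traj.participant,
                "condition": traj.condition,
                "mean_speed": float(speed[rot_window].mean()),
                "within_sd": float(speed[rot_window].std(ddof=1)),
                "plateau_speed": float(speed[stim_window].mean()),
            }
        )
    df = pd.DataFrame(rows)
    rot = df.loc[df["condition"] != "stationary"]
    per = (
        rot.groupby(["participant", "condition"], sort=True)
        .agg(mean_speed=("mean_speed", "mean"), mean_within_sd=("within_sd", "mean"))
        .reset_index()
        .rename(columns={"condition": "direction"})
    )
    flags = set()
    plateau = df.groupby(["participant", "condition"])["plateau_speed"].mean().reset_index()
    for _, r in plateau.iterrows():
        if r["condition"] == "stationary" and r["plateau_speed"] > plateau_flag_deg_s:
            flags.add(r["participant"])
        if r["condition"] != "stationary" and r["plateau_speed"] < plateau_flag_deg_s:
            flags.add(r["participant"])
    cohort_var = float(per.groupby("participant")["mean_within_sd"].mean().mean())
    return SpeedSummary(per_participant=per, flagged=sorted(flags), cohort_variability=cohort_var)


def speed_threshold_regression(
    speed_summary: SpeedSummary,
    threshold_table: pd.DataFrame,
    direction: str,
) -> Dict[str, float]:
    """OLS of per-participant threshold on mean head speed when rotating
    ``direction``.  Thresholds are the participant's mean over kept cells
    with that head rotation (collapsed across stimulus direction).
    Returns adjusted R^2, F, dfs and p."""
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    speeds = speed_summary.per_participant
    sp = speeds.loc[speeds["direction"] == direction].set_index("participant")["mean_speed"]
    kept = threshold_table.loc[
        (~threshold_table["excluded"]) & (threshold_table["head_rotation"] == direction)
    ]
    th = kept.groupby("participant")["threshold"].mean()
    joined = pd.concat([sp, th], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        raise ValueError(f"need at least 3 participants with both measures, got {n}")
    x = joined["mean_speed"].to_numpy()
    y = joined["threshold"].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("head speed is constant across participants")
    slope, intercept, r, p, _ = sps.linregress(x, y)
    r2 = r**2
    df_den = n - 2
    f = r2 / (1 - r2) * df_den if r2 < 1 else math.inf
    adj_r2 = 1 - (1 - r2) * (n - 1) / (n - 2)
    return {
        "adj_r2": float(adj_r2),
        "F": float(f),
        "df_num": 1,
        "df_den": int(df_den),
        "p": float(p),
        "n": n,
        "slope": float(slope),
        "intercept": float(intercept),
    }
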