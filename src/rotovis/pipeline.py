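"""End-to-end orchestration: simulate -> screen -> fit -> bootstrap -> stats.

``run_pipeline`` is a pure function of its :class:`RunConfig`: identical
configs produce byte-identical CSV outputs.  Stages write their outputs as
they complete, so a failure in a late stage (raised as a stage-tagged
:class:`StageError`) leaves earlier artifacts intact.
``recover_parameters`` closes the validation loop by comparing a run's
estimates against the generating parameters saved with it.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from . import observer as obs
from . import psychfit as pf
from . import stats as st
from .quest import QuestConfig

__all__ = ["RunConfig", "StageError", "run_pipeline", "recover_parameters", "make_figures"]


class StageError(RuntimeError):
    """Pipeline failure tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    experiment: str = "exp1"
    n_participants: int = 20
    seed: int = 0
    bootstrap_seed: int = 1
    trials_per_cell: int = 30
    population: Optional[dict] = None  # overrides for PopulationSpec fields
    quest: Optional[dict] = None  # overrides for QuestConfig fields
    fixed_lapse_accuracy: float = 0.0
    fixed_lapse_directional: float = 0.01
    bootstrap_B: int = 1000
    with_trajectories: bool = True
    figures: bool = True
    out_dir: str = "run"

    def population_spec(self) -> obs.PopulationSpec:
        base = obs.exp1_population() if self.experiment == "exp1" else obs.exp2_population()
        if self.population:
            base = dataclasses.replace(base, **self.population)
        return base

    def quest_config(self) -> QuestConfig:
        return QuestConfig(**(self.quest or {}))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> Path:
    """Run the full closed-loop study simulation and analysis.

    Writes trials.csv, trajectories.csv (optional), thresholds.csv,
    pse_bootstrap.csv (direction task only), stats.json, truth.json,
    config.yaml, log.json and summary figures into ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log: List[dict] = []

    def _stage(name):
        t0 = time.perf_counter()

        def done(**extra):
            log.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3), **extra})
            (out / "log.json").write_text(json.dumps(log, indent=2))

        return done

    done = _stage("simulate")
    try:
        cohort = obs.generate_cohort(
            config.experiment,
            config.n_participants,
            population_spec=config.population_spec(),
            seed=config.seed,
            trials_per_cell=config.trials_per_cell,
            quest_config=config.quest_config(),
            with_trajectories=config.with_trajectories,
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", str(e)) from e
    _write_csv(cohort.trials, out / "trials.csv")
    cohort.true_params.to_json(out / "truth.json", orient="records", indent=2)
    if config.with_trajectories:
        _write_csv(_trajectories_frame(cohort.trajectories), out / "trajectories.csv")
    done(seed=config.seed, n_trials=len(cohort.trials))

    done = _stage("fit")
    try:
        table = pf.build_threshold_table(
            cohort.trials,
            cohort.traces,
            fixed_lapse=config.fixed_lapse_accuracy,
            intensity_ceiling=config.quest_config().intensity_ceiling,
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("fit", str(e)) from e
    _write_csv(table, out / "thresholds.csv")
    done(n_excluded=int(table["excluded"].sum()))

    boot = None
    if config.experiment == "exp1":
        done = _stage("pse_bootstrap")
        try:
            boot = pf.bootstrap_super_subject(
                cohort.trials,
                B=config.bootstrap_B,
                seed=config.bootstrap_seed,
                fixed_lapse=config.fixed_lapse_directional,
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("pse_bootstrap", str(e)) from e
        _write_csv(boot, out / "pse_bootstrap.csv")
        done(B=config.bootstrap_B)

    done = _stage("stats")
    try:
        anova = st.rm_anova_2x3(table)
        posthocs = st.posthoc_bonferroni(table)
        lme = st.lme_stepwise(table)
        report = {
            "anova": [asdict(a) for a in anova],
            "posthoc_bonferroni": [asdict(p) for p in posthocs],
            "lme": {
                "formulas": lme.formulas,
                "logliks": lme.logliks,
                "steps": [asdict(s) for s in lme.steps],
                "winning_formula": lme.winning_formula,
                "coefficients": [asdict(c) for c in lme.coefficients],
                "singular": lme.singular,
            },
            "notes": {
                "anova_sample": "listwise deletion (complete 6-cell participants only)",
                "lme_sample": "all available cells",
            },
        }
        if config.with_trajectories:
            speed = st.summarize_head_speed(cohort.trajectories)
            report["head_speed"] = {
                "per_participant": speed.per_participant.to_dict(orient="records"),
                "flagged": speed.flagged,
                "cohort_variability": speed.cohort_variability,
            }
            report["speed_threshold_regression"] = {
                d: st.speed_threshold_regression(speed, table, d) for d in ("left", "right")
            }
    except ValueError as e:
        raise StageError("stats", str(e)) from e
    (out / "stats.json").write_text(json.dumps(report, indent=2))
    done()

    if config.figures:
        done = _stage("figures")
        make_figures(out, cohort, table, boot)
        done()
    return out


def _trajectories_frame(trajectories) -> pd.DataFrame:
    frames = []
    for i, tr in enumerate(trajectories):
        frames.append(
            pd.DataFrame(
                {
                    "participant": tr.participant,
                    "block": tr.block,
                    "trial_index": tr.trial_index,
                    "condition": tr.condition,
                    "time_s": tr.time_s,
                    "yaw_deg": tr.yaw_deg,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def make_figures(out: Path, cohort, table: pd.DataFrame, boot: Optional[pd.DataFrame]) -> None:
    """Summary figures: threshold bars with participant dots, trajectory
    spaghetti with mean +/- SEM, and PSE bootstrap CI bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    collapsed = pf.collapse_directions(table)
    order = ["stationary", "congruent", "incongruent"]
    fig, ax = plt.subplots(figsize=(4, 3.2))
    means = collapsed.groupby("congruence")["threshold"].mean().reindex(order)
    sems = collapsed.groupby("congruence")["threshold"].sem().reindex(order)
    ax.bar(order, means, yerr=sems, color="0.8", edgecolor="k", capsize=3)
    for i, cond in enumerate(order):
        y = collapsed.loc[collapsed["congruence"] == cond, "threshold"]
        ax.plot(np.full(len(y), i) + np.random.default_rng(0).uniform(-0.08, 0.08, len(y)),
                y, "o", ms=3, color="tab:blue", alpha=0.6)
    ax.set_ylabel("threshold (signal intensity)")
    fig.tight_layout()
    fig.savefig(out / "fig_thresholds.png", dpi=120)
    plt.close(fig)

    if cohort.trajectories:
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        rot = [t for t in cohort.trajectories if t.condition != "stationary"][:200]
        for tr in rot:
            ax.plot(tr.time_s, np.abs(tr.yaw_deg), color="0.8", lw=0.3)
        if rot:
            tmin = min(len(t.time_s) for t in rot)
            stack = np.stack([np.abs(t.yaw_deg[:tmin]) for t in rot])
            tt = rot[0].time_s[:tmin]
            m, s = stack.mean(0), stack.std(0) / np.sqrt(stack.shape[0])
            ax.plot(tt, m, color="k")
            ax.fill_between(tt, m - s, m + s, color="k", alpha=0.3)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("|yaw| (deg)")
        fig.tight_layout()
        fig.savefig(out / "fig_trajectories.png", dpi=120)
        plt.close(fig)

    if boot is not None:
        fig, ax = plt.subplots(figsize=(4, 3.2))
        for i, (_, row) in enumerate(boot.iterrows()):
            ax.errorbar(
                i, row["pse_boot_mean"],
                yerr=[[row["pse_boot_mean"] - row["ci_low"]], [row["ci_high"] - row["pse_boot_mean"]]],
                fmt="o", capsize=4, color="tab:red",
            )
        ax.axhline(0, color="0.5", ls="--", lw=0.8)
        ax.set_xticks(range(len(boot)))
        ax.set_xticklabels(boot["head_rotation"])
        ax.set_ylabel("PSE (signed intensity)")
        fig.tight_layout()
        fig.savefig(out / "fig_pse_bootstrap.png", dpi=120)
        plt.close(fig)


def recover_parameters(
    run_dir: str | Path,
    truth_path: str | Path | None = None,
    tol_mu: float = 0.05,
    tol_delta: float = 0.05,
) -> pd.DataFrame:
    """Compare a run's estimates with its generating parameters.

    Per-condition group-mean thresholds are compared against the expected
    measured threshold: the population threshold itself for the detection
    task, and a bias-adjusted value (mu - delta for congruent, mu + delta
    for incongruent) for the direction task, where the criterion shift
    moves the accuracy-defined threshold.  If a PSE bootstrap is present,
    the bias delta is recovered as (PSE_left - PSE_right) / 2.  Writes and
    returns a tidy recovery table with pass/fail at the given tolerances.
    """
    run_dir = Path(run_dir)
    truth_path = Path(truth_path) if truth_path else run_dir / "truth.json"
    if not truth_path.exists():
        raise FileNotFoundError(f"truth file not found: {truth_path}")
    truth = pd.read_json(truth_path)
    config = RunConfig.from_yaml(run_dir / "config.yaml")
    table = pd.read_csv(run_dir / "thresholds.csv")
    collapsed = pf.collapse_directions(table)
    est = collapsed.groupby("congruence")["threshold"].mean()

    delta_true = float(truth["head_bias_delta"].mean())
    rows = []
    for cond in ("stationary", "congruent", "incongruent"):
        mu_true = float(truth[f"mu_{cond}"].mean())
        expected = mu_true
        if config.experiment == "exp1":
            shift = {"stationary": 0.0, "congruent": -delta_true, "incongruent": delta_true}[cond]
            expected = mu_true + shift
        e = float(est.get(cond, np.nan))
        rows.append(
            {
                "quantity": f"threshold_{cond}",
                "true": expected,
                "estimated": e,
                "error": e - expected,
                "tolerance": tol_mu,
                "passed": bool(abs(e - expected) <= tol_mu),
            }
        )
    boot_path = run_dir / "pse_bootstrap.csv"
    if boot_path.exists():
        boot = pd.read_csv(boot_path).set_index("head_rotation")
        delta_est = float((boot.loc["left", "pse"] - boot.loc["right", "pse"]) / 2)
        rows.append(
            {
                "quantity": "head_bias_delta",
                "true": delta_true,
                "estimated": delta_est,
                "error": delta_est - delta_true,
                "tolerance": tol_delta,
                "passed": bool(abs(delta_est - delta_true) <= tol_delta),
            }
        )
    report = pd.DataFrame(rows)
    report.to_csv(run_dir / "recovery.csv", index=False)
    return report
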