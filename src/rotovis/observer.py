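"""Synthetic observers: response models, head kinematics, closed-loop runs.

A simulated participant carries per-condition detection thresholds (on the
[0, 1] signal-intensity scale), a psychometric slope, a lapse rate, and a
head-direction response bias.  Two response models are provided:

* a *direction* model for the left/right judgement task, a cumulative
  Gaussian over signed intensity whose location is shifted by
  ``head_bias_delta`` in the direction of head rotation (a criterion/PSE
  shift); and
* a *detection* model for the upper/lower hemifield task, a 2AFC accuracy
  function with guess rate 0.5 whose 75% point is the condition threshold.

``run_participant`` closes the loop: it builds the factorial schedule,
runs one QUEST staircase per (direction x rotation) cell per session,
places each trial at the staircase's current estimate, draws the response,
and logs trial records, staircase traces and head trajectories.
``generate_cohort`` samples a population of such observers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, List, Literal, Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import TrialPlan, build_schedule, schedule_to_frame
from . import quest as q

__all__ = [
    "ObserverParams",
    "PopulationSpec",
    "HeadTrajectory",
    "ParticipantRun",
    "Cohort",
    "respond_direction",
    "respond_detection",
    "generate_head_trajectory",
    "run_participant",
    "generate_cohort",
    "exp1_population",
    "exp2_population",
]

SAMPLE_HZ = 90.0
RAMP_S = 0.3  # linear acceleration to plateau
STATIONARY_JITTER_DEG_S = 0.5

_HEAD_SIGN = {"left": -1, "right": 1, "stationary": 0}
_DIR_SIGN = {"left": -1, "right": 1}


def _phi(x: float) -> float:
    """Standard normal CDF (scalar fast path)."""
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@dataclass(frozen=True)
class ObserverParams:
    """Generating parameters of one simulated participant."""

    mu_by_condition: Dict[str, float]
    sigma: float = 0.10
    lapse: float = 0.02
    head_bias_delta: float = 0.0
    speed_mean_deg_s: float = 38.0
    speed_sd_deg_s: float = 2.0
    onset_latency_s: float = 0.05

    def __post_init__(self) -> None:
        for cond in ("congruent", "incongruent", "stationary"):
            mu = self.mu_by_condition.get(cond)
            if mu is None or not (0 < mu):
                raise ValueError(f"mu_by_condition[{cond!r}] must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0 <= self.lapse <= 0.06):
            raise ValueError("lapse must lie in [0, 0.06]")
        if self.head_bias_delta < 0:
            raise ValueError("head_bias_delta must be non-negative")


@lru_cache(maxsize=64)
def _criterion_z(lapse: float, target_p: float) -> float:
    return float(norm.ppf((target_p - lapse / 2) / (1 - lapse)))


def _direction_sigma(params: ObserverParams, condition: str, target_p: float = 0.75) -> float:
    """Slope of the direction model giving 75% correct at the condition
    threshold (absent bias): solves lapse/2 + (1-lapse)*Phi(mu/sigma) =
    target_p for sigma."""
    return params.mu_by_condition[condition] / _criterion_z(params.lapse, target_p)


def respond_direction(
    signed_intensity: float,
    head_dir: int,
    params: ObserverParams,
    rng: np.random.Generator,
    sigma: float | None = None,
) -> str:
    """Left/right judgement of signed intensity (leftward negative).

    P(respond right) = lapse/2 + (1 - lapse) *
    Phi((signed_intensity + head_bias_delta * head_dir) / sigma):
    head rotation shifts the decision axis toward its own direction.
    """
    if abs(signed_intensity) > 1:
        raise ValueError("signed_intensity must lie in [-1, 1]")
    if head_dir not in (-1, 0, 1):
        raise ValueError("head_dir must be -1, 0 or +1")
    s = params.sigma if sigma is None else sigma
    shifted = signed_intensity + params.head_bias_delta * head_dir
    p_right = params.lapse / 2 + (1 - params.lapse) * _phi(shifted / s)
    return "right" if rng.random() < p_right else "left"


def respond_detection(
    intensity: float,
    condition: str,
    params: ObserverParams,
    rng: np.random.Generator,
) -> bool:
    """Correct/incorrect on the hemifield detection task.

    P(correct) = 0.5 + (0.5 - lapse) * Phi((intensity - mu_condition) /
    sigma): chance at zero signal, 75% at the condition threshold when the
    lapse rate is zero.
    """
    if not (0 <= intensity <= 1):
        raise ValueError("intensity must lie in [0, 1]")
    if condition not in params.mu_by_condition:
        raise ValueError(f"unknown condition {condition!r}")
    mu = params.mu_by_condition[condition]
    p = 0.5 + (0.5 - params.lapse) * _phi((intensity - mu) / params.sigma)
    return bool(rng.random() < p)


@dataclass(frozen=True)
class HeadTrajectory:
    """Yaw samples (right positive) for one trial at 90 Hz."""

    time_s: np.ndarray
    yaw_deg: np.ndarray
    condition: str  # head rotation label
    participant: str = ""
    block: int = 1
    trial_index: int = 0
    stim_onset_s: float = 1.2
    stim_offset_s: float = 1.6

    def speed_deg_s(self) -> np.ndarray:
        """Instantaneous absolute yaw speed from first differences."""
        dt = np.diff(self.time_s)
        return np.abs(np.diff(self.yaw_deg)) / dt


def generate_head_trajectory(
    plan: TrialPlan,
    params: ObserverParams,
    rng: np.random.Generator,
) -> HeadTrajectory:
    """Trapezoidal yaw-velocity profile for one trial.

    Rotation trials: zero velocity until guide arrival (1 s) plus onset
    latency, a linear ramp (0.3 s) to a per-trial plateau speed drawn from
    Normal(speed_mean, speed_sd), held through stimulus offset.  Stationary
    trials emit zero-mean velocity jitter (SD 0.5 deg/s).  Small jitter is
    superimposed on rotation trials too.  The whole velocity trace is
    signed by the commanded direction, so left and right plans generated
    from the same RNG state are exact mirror images.
    """
    t_end = plan.stimulus_onset_s + plan.stimulus_duration_s
    n = int(round(t_end * SAMPLE_HZ)) + 1
    t = np.arange(n) / SAMPLE_HZ
    jitter = rng.normal(0.0, STATIONARY_JITTER_DEG_S, size=n)
    if plan.head_rotation == "stationary":
        vel = jitter
    else:
        plateau = rng.normal(params.speed_mean_deg_s, params.speed_sd_deg_s)
        plateau = max(plateau, 1.0)
        t0 = 1.0 + params.onset_latency_s  # guide arrival + latency
        ramp = np.clip((t - t0) / RAMP_S, 0.0, 1.0)
        vel = (plateau * ramp + jitter) * _HEAD_SIGN[plan.head_rotation]
    yaw = np.concatenate([[0.0], np.cumsum(vel[:-1]) / SAMPLE_HZ])
    return HeadTrajectory(
        time_s=t,
        yaw_deg=yaw,
        condition=plan.head_rotation,
        block=plan.block,
        trial_index=plan.trial_index,
        stim_onset_s=plan.stimulus_onset_s,
        stim_offset_s=t_end,
    )


@dataclass
class ParticipantRun:
    participant: str
    experiment: str
    trials: pd.DataFrame
    trajectories: List[HeadTrajectory]
    traces: Dict[tuple, pd.DataFrame]  # (block, stim_direction, head_rotation)
    params: ObserverParams


def run_participant(
    experiment: str,
    params: ObserverParams,
    seed: int,
    participant: str = "p00",
    trials_per_cell: int = 30,
    quest_config: Optional[q.QuestConfig] = None,
    prior_mean_intensity: float = 0.3,
    prior_sd_log: float = 0.5,
    with_trajectories: bool = True,
) -> ParticipantRun:
    """Closed-loop simulation of one participant (two sessions).

    One QUEST staircase per (direction x rotation) cell per session places
    every trial at its current estimate; the response comes from the
    direction model (exp1; correctness judged against the true stimulus
    direction, so the head bias degrades incongruent accuracy) or the
    detection model (exp2).
    """
    rng = np.random.default_rng(seed)
    cfg = quest_config or q.QuestConfig()
    plans = build_schedule(experiment, seed=int(rng.integers(2**31)), trials_per_cell=trials_per_cell)
    prior_mean_log = math.log10(prior_mean_intensity)

    states: Dict[tuple, q.QuestState] = {}
    trace_rows: Dict[tuple, list] = {}
    records = []
    trajectories: List[HeadTrajectory] = []
    for plan in plans:
        key = (plan.block, plan.stim_direction, plan.head_rotation)
        if key not in states:
            states[key] = q.quest_init(prior_mean_log, prior_sd_log, cfg)
            trace_rows[key] = []
        state = states[key]
        x = q.quest_next_intensity(state)
        dsign = _DIR_SIGN[plan.stim_direction]
        hsign = _HEAD_SIGN[plan.head_rotation]
        if experiment == "exp1":
            sigma_c = _direction_sigma(params, plan.congruence, cfg.target_p)
            response = respond_direction(x * dsign, hsign, params, rng, sigma=sigma_c)
            correct = response == plan.stim_direction
        else:
            correct = respond_detection(x, plan.congruence, params, rng)
            other = "lower" if plan.hemifield == "upper" else "upper"
            response = plan.hemifield if correct else other
        states[key] = q.quest_update(state, x, correct)
        trace_rows[key].append(
            {
                "trial": len(trace_rows[key]),
                "intensity": x,
                "correct": correct,
                "estimate": q.quest_estimate(states[key]),
            }
        )
        records.append(
            {
                "participant": participant,
                "experiment": experiment,
                "session": plan.block,
                "trial_index": plan.trial_index,
                "stim_direction": plan.stim_direction,
                "head_rotation": plan.head_rotation,
                "congruence": plan.congruence,
                "hemifield": plan.hemifield,
                "presented_intensity": x,
                "signed_intensity": x * dsign,
                "response": response,
                "correct": correct,
            }
        )
        if with_trajectories:
            traj = generate_head_trajectory(plan, params, rng)
            trajectories.append(replace(traj, participant=participant))

    traces = {k: pd.DataFrame(v) for k, v in trace_rows.items()}
    return ParticipantRun(
        participant=participant,
        experiment=experiment,
        trials=pd.DataFrame(records),
        trajectories=trajectories,
        traces=traces,
        params=params,
    )


@dataclass(frozen=True)
class PopulationSpec:
    """Population-level generating distribution for a cohort.

    Per-participant threshold maps are sampled log-normally: a shared
    participant scale factor (coefficient of variation
    ``mu_participant_cv``, the random intercept the group models assume)
    multiplies every condition mean, and a small independent
    condition-level jitter (``mu_condition_cv``) is applied on top.  Slope
    and bias are sampled log-normally with their own CVs; the lapse rate is
    fixed.
    """

    mu_by_condition: Dict[str, float]
    sigma: float = 0.10
    lapse: float = 0.02
    head_bias_delta: float = 0.0
    speed_mean_deg_s: float = 38.0
    speed_sd_deg_s: float = 2.0
    onset_latency_s: float = 0.05
    mu_participant_cv: float = 0.20
    mu_condition_cv: float = 0.03
    sigma_cv: float = 0.20
    delta_cv: float = 0.20

    def __post_init__(self) -> None:
        for name in ("mu_participant_cv", "mu_condition_cv", "sigma_cv", "delta_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def sample_participant(self, rng: np.random.Generator) -> ObserverParams:
        def lognorm(mean: float, cv: float) -> float:
            if cv == 0 or mean == 0:
                return mean
            s2 = math.log1p(cv**2)
            return float(mean * np.exp(rng.normal(-s2 / 2, math.sqrt(s2))))

        scale = lognorm(1.0, self.mu_participant_cv)
        mu = {
            c: min(m * scale * lognorm(1.0, self.mu_condition_cv), 1.5)
            for c, m in self.mu_by_condition.items()
        }
        return ObserverParams(
            mu_by_condition=mu,
            sigma=lognorm(self.sigma, self.sigma_cv),
            lapse=self.lapse,
            head_bias_delta=lognorm(self.head_bias_delta, self.delta_cv),
            speed_mean_deg_s=lognorm(self.speed_mean_deg_s, 0.05),
            speed_sd_deg_s=self.speed_sd_deg_s,
            onset_latency_s=self.onset_latency_s,
        )


def exp1_population(**overrides) -> PopulationSpec:
    """Default direction-task population.

    Condition thresholds 0.30 / 0.33 / 0.36 (stationary / congruent /
    incongruent) with a 0.10 criterion bias toward the head direction:
    under the direction task the bias lowers the measured congruent
    threshold by ~delta and raises the incongruent one by ~delta, yielding
    measured group effects of about -0.07 (congruent - stationary) and
    +0.16 (incongruent - stationary).
    """
    defaults = dict(
        mu_by_condition={"stationary": 0.30, "congruent": 0.33, "incongruent": 0.36},
        head_bias_delta=0.10,
    )
    defaults.update(overrides)
    return PopulationSpec(**defaults)


def exp2_population(**overrides) -> PopulationSpec:
    """Default detection-task population: both rotation conditions elevated
    by 0.05 over stationary, no usable response bias on the hemifield task."""
    defaults = dict(
        mu_by_condition={"stationary": 0.25, "congruent": 0.30, "incongruent": 0.30},
        head_bias_delta=0.0,
    )
    defaults.update(overrides)
    return PopulationSpec(**defaults)


@dataclass
class Cohort:
    experiment: str
    trials: pd.DataFrame
    trajectories: List[HeadTrajectory]
    traces: Dict[str, Dict[tuple, pd.DataFrame]]  # participant -> traces
    true_params: pd.DataFrame
    population: PopulationSpec
    seed: int


def generate_cohort(
    experiment: str,
    n_participants: int,
    population_spec: Optional[PopulationSpec] = None,
    seed: int = 0,
    trials_per_cell: int = 30,
    quest_config: Optional[q.QuestConfig] = None,
    with_trajectories: bool = False,
) -> Cohort:
    """Simulate a cohort: sample observer parameters per participant and
    run each through the closed loop.  Deterministic under (seed, spec)."""
    if n_participants < 1:
        raise ValueError("n_participants must be positive")
    spec = population_spec or (
        exp1_population() if experiment == "exp1" else exp2_population()
    )
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_participants)
    all_trials = []
    all_traj: List[HeadTrajectory] = []
    traces: Dict[str, Dict[tuple, pd.DataFrame]] = {}
    truth_rows = []
    for i, child in enumerate(children):
        pid = f"p{i:02d}"
        prng = np.random.default_rng(child)
        params = spec.sample_participant(prng)
        run = run_participant(
            experiment,
            params,
            seed=int(prng.integers(2**31)),
            participant=pid,
            trials_per_cell=trials_per_cell,
            quest_config=quest_config,
            with_trajectories=with_trajectories,
        )
        all_trials.append(run.trials)
        all_traj.extend(run.trajectories)
        traces[pid] = run.traces
        row = {"participant": pid, **{f"mu_{c}": v for c, v in params.mu_by_condition.items()}}
        row.update(
            sigma=params.sigma,
            lapse=params.lapse,
            head_bias_delta=params.head_bias_delta,
            speed_mean_deg_s=params.speed_mean_deg_s,
        )
        truth_rows.append(row)
    return Cohort(
        experiment=experiment,
        trials=pd.concat(all_trials, ignore_index=True),
        trajectories=all_traj,
        traces=traces,
        true_params=pd.DataFrame(truth_rows),
        population=spec,
        seed=seed,
    )
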