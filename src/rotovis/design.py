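"""Factorial trial schedules.

Both experiments cross 2 stimulus directions x 3 head rotations (left,
right, stationary) at 30 trials per cell per block, two blocks, with trial
order shuffled uniformly within each block.  The hemifield experiment
additionally splits each cell equally between upper and lower stimulus
placement.  A short fixed-order practice block (10 stationary, 10
congruent, 10 incongruent trials) precedes the experiment proper.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import List, Literal

import numpy as np
import pandas as pd

__all__ = [
    "TrialPlan",
    "classify_congruence",
    "build_schedule",
    "build_practice_schedule",
    "schedule_to_frame",
]

Direction = Literal["left", "right"]
Rotation = Literal["left", "right", "stationary"]

GUIDE_SPEED_DEG_S = 40.0
GUIDE_ARRIVAL_S = 1.0
STIM_DURATION_S = 0.4
ITI_S = 0.9
# Stimulus onset measured from guide entry: 1.2 s in the direction task;
# in the detection task presentation is 1.2 s after guide *arrival* (1 s),
# i.e. 2.2 s absolute, to land within the constant-velocity plateau.
STIM_ONSET_S = {"exp1": 1.2, "exp2": 2.2}

_DIRECTIONS: tuple[Direction, ...] = ("left", "right")
_ROTATIONS: tuple[Rotation, ...] = ("left", "right", "stationary")


def classify_congruence(stim_direction: str, head_rotation: str) -> str:
    """Label a (visual direction, head rotation) pairing.

    stationary head -> "stationary"; matching directions -> "congruent";
    opposite directions -> "incongruent".
    """
    if stim_direction not in _DIRECTIONS:
        raise ValueError(f"invalid stimulus direction {stim_direction!r}")
    if head_rotation not in _ROTATIONS:
        raise ValueError(f"invalid head rotation {head_rotation!r}")
    if head_rotation == "stationary":
        return "stationary"
    return "congruent" if stim_direction == head_rotation else "incongruent"


@dataclass(frozen=True)
class TrialPlan:
    experiment: str
    block: int
    trial_index: int
    stim_direction: Direction
    head_rotation: Rotation
    congruence: str
    hemifield: str  # "upper" | "lower" | "n/a"
    guide_speed_deg_s: float = GUIDE_SPEED_DEG_S
    stimulus_onset_s: float = 1.2
    stimulus_duration_s: float = STIM_DURATION_S
    iti_s: float = ITI_S

    def __post_init__(self) -> None:
        expected = classify_congruence(self.stim_direction, self.head_rotation)
        if self.congruence != expected:
            raise ValueError(
                f"congruence {self.congruence!r} inconsistent with "
                f"({self.stim_direction}, {self.head_rotation})"
            )
        if (self.hemifield == "n/a") != (self.experiment == "exp1"):
            raise ValueError("hemifield is n/a exactly for exp1")


def _check_experiment(experiment: str) -> None:
    if experiment not in ("exp1", "exp2"):
        raise ValueError(f"unknown experiment {experiment!r}")


def build_schedule(
    experiment: str,
    seed: int,
    trials_per_cell: int = 30,
    n_blocks: int = 2,
) -> List[TrialPlan]:
    """Full factorial schedule: ``trials_per_cell`` trials per
    (direction x rotation) cell per block, shuffled uniformly within block.

    For the hemifield experiment each cell is split half upper / half
    lower (``trials_per_cell`` must be even).
    """
    _check_experiment(experiment)
    if trials_per_cell < 1:
        raise ValueError("trials_per_cell must be positive")
    if experiment == "exp2" and trials_per_cell % 2:
        raise ValueError("exp2 needs an even trials_per_cell for the hemifield split")
    rng = np.random.default_rng(seed)
    onset = STIM_ONSET_S[experiment]
    plans: List[TrialPlan] = []
    for block in range(1, n_blocks + 1):
        cells = []
        for d in _DIRECTIONS:
            for r in _ROTATIONS:
                for i in range(trials_per_cell):
                    if experiment == "exp1":
                        hemi = "n/a"
                    else:
                        hemi = "upper" if i < trials_per_cell // 2 else "lower"
                    cells.append((d, r, hemi))
        order = rng.permutation(len(cells))
        for idx, j in enumerate(order):
            d, r, hemi = cells[j]
            plans.append(
                TrialPlan(
                    experiment=experiment,
                    block=block,
                    trial_index=idx,
                    stim_direction=d,
                    head_rotation=r,
                    congruence=classify_congruence(d, r),
                    hemifield=hemi,
                    stimulus_onset_s=onset,
                )
            )
    return plans


def build_practice_schedule(experiment: str = "exp1") -> List[TrialPlan]:
    """Fixed-order practice block: 10 stationary, 10 congruent and 10
    incongruent trials, each with 5 leftward and 5 rightward stimuli."""
    _check_experiment(experiment)
    onset = STIM_ONSET_S[experiment]
    plans: List[TrialPlan] = []
    idx = 0
    for congruence in ("stationary", "congruent", "incongruent"):
        for rep in range(5):
            for d in _DIRECTIONS:
                if congruence == "stationary":
                    r: Rotation = "stationary"
                elif congruence == "congruent":
                    r = d
                else:
                    r = "right" if d == "left" else "left"
                hemi = "n/a"
                if experiment == "exp2":
                    hemi = "upper" if rep % 2 == 0 else "lower"
                plans.append(
                    TrialPlan(
                        experiment=experiment,
                        block=0,
                        trial_index=idx,
                        stim_direction=d,
                        head_rotation=r,
                        congruence=congruence,
                        hemifield=hemi,
                        stimulus_onset_s=onset,
                    )
                )
                idx += 1
    return plans


def schedule_to_frame(plans: List[TrialPlan]) -> pd.DataFrame:
    """Serialize a schedule as a long-format DataFrame (one row per trial)."""
    return pd.DataFrame([asdict(p) for p in plans])
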