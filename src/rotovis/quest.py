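"""Bayesian adaptive staircase (QUEST) holding performance at 75% correct.

A grid posterior is maintained over log10 threshold.  The assumed
psychometric function is a Weibull on the log10-intensity axis with guess
rate 0.5 (two-alternative task) and a small lapse rate; it is shifted so
that the threshold parameter marks the target-probability point (75%), so
each trial is placed where the observer is expected to be 75% correct and
the final estimate is directly the 75%-correct intensity.

Updates are functional: ``quest_update`` returns a new state, leaving the
input untouched, so posteriors can be replayed and compared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "QuestConfig",
    "QuestState",
    "quest_init",
    "quest_next_intensity",
    "quest_update",
    "quest_estimate",
]


@dataclass(frozen=True)
class QuestConfig:
    """Internal-model and grid settings for the staircase.

    slope/guess/lapse parameterize the assumed Weibull; target_p is the
    performance level the procedure tracks; the grid spans log10 intensity
    with the stated step; intensity bounds clamp trial placement on the
    linear [0, 1] signal scale.
    """

    slope: float = 3.5
    guess: float = 0.5
    lapse: float = 0.01
    target_p: float = 0.75
    grid_lo: float = -3.0
    grid_hi: float = 0.0
    grid_step: float = 0.005
    intensity_floor: float = 0.001
    intensity_ceiling: float = 1.0
    placement: str = "mean"  # "mean" | "mode"

    def __post_init__(self) -> None:
        if not (0 < self.target_p < 1):
            raise ValueError("target_p must lie in (0, 1)")
        if not (self.guess < self.target_p < 1 - self.lapse):
            raise ValueError("target_p must lie between guess and 1 - lapse")
        if not (0 < self.intensity_floor < self.intensity_ceiling <= 1):
            raise ValueError("intensity bounds must satisfy 0 < floor < ceiling <= 1")

    @property
    def threshold_offset(self) -> float:
        """Shift (log10 units) putting the target probability at threshold.

        Solves guess + (1-guess-lapse) * (1 - exp(-10**(slope*eps))) =
        target_p for eps.
        """
        frac = (self.target_p - self.guess) / (1 - self.guess - self.lapse)
        return math.log10(-math.log1p(-frac)) / self.slope


@dataclass(frozen=True)
class QuestState:
    grid: np.ndarray  # log10 intensity, strictly increasing
    log_posterior: np.ndarray
    config: QuestConfig
    trial_count: int = 0

    @cached_property
    def posterior(self) -> np.ndarray:
        p = np.exp(self.log_posterior - self.log_posterior.max())
        return p / p.sum()

    @cached_property
    def posterior_mean_log(self) -> float:
        return float(np.dot(self.posterior, self.grid))


def quest_init(
    prior_mean_log: float,
    prior_sd_log: float,
    config: QuestConfig | None = None,
) -> QuestState:
    """Fresh staircase with a Gaussian prior over log10 threshold."""
    if prior_sd_log <= 0:
        raise ValueError("prior_sd_log must be positive")
    cfg = config or QuestConfig()
    n = int(round((cfg.grid_hi - cfg.grid_lo) / cfg.grid_step)) + 1
    grid = cfg.grid_lo + cfg.grid_step * np.arange(n)
    log_prior = -0.5 * ((grid - prior_mean_log) / prior_sd_log) ** 2
    log_prior -= logsumexp(log_prior)
    return QuestState(grid=grid, log_posterior=log_prior, config=cfg, trial_count=0)


def p_correct(log_intensity: float | np.ndarray, log_threshold: np.ndarray, cfg: QuestConfig) -> np.ndarray:
    """Assumed P(correct) at log10 intensity given log10 threshold."""
    x = np.asarray(log_intensity) - np.asarray(log_threshold) + cfg.threshold_offset
    f = 1.0 - np.exp(-np.power(10.0, cfg.slope * x))
    return cfg.guess + (1 - cfg.guess - cfg.lapse) * f


def quest_next_intensity(state: QuestState) -> float:
    """Linear intensity for the next trial (posterior mean placement,
    clamped to the configured intensity bounds)."""
    cfg = state.config
    if cfg.placement == "mode":
        loc = float(state.grid[np.argmax(state.log_posterior)])
    else:
        loc = state.posterior_mean_log
    return float(min(max(10.0 ** loc, cfg.intensity_floor), cfg.intensity_ceiling))


def quest_update(state: QuestState, tested_intensity: float, correct: bool) -> QuestState:
    """Bayes update after one trial at ``tested_intensity``."""
    if not np.isfinite(tested_intensity) or tested_intensity <= 0:
        raise ValueError(f"tested_intensity must be positive and finite, got {tested_intensity}")
    cfg = state.config
    p = p_correct(math.log10(tested_intensity), state.grid, cfg)
    like = p if correct else 1.0 - p
    log_post = state.log_posterior + np.log(np.clip(like, 1e-300, None))
    log_post = log_post - logsumexp(log_post)
    return replace(state, log_posterior=log_post, trial_count=state.trial_count + 1)


def quest_estimate(state: QuestState) -> float:
    """Final threshold estimate: posterior mean on the log scale,
    exponentiated back to linear intensity."""
    if state.trial_count < 1:
        raise ValueError("cannot estimate a threshold before any trials")
    return float(10.0 ** state.posterior_mean_log)
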