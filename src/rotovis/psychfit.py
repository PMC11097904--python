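"""Psychometric estimation: screening, threshold fits, PSE fits, bootstrap.

Two cumulative-Gaussian models are fitted by maximum likelihood:

* *accuracy*: P(correct | x) = 0.5 + (0.5 - lapse) * Phi((x - mu) / sigma)
  on unsigned intensity, guess rate fixed at 0.5.  With zero lapse the
  fitted mu is exactly the 75%-correct intensity, the dependent threshold
  measure throughout.
* *directional*: P(right | x) = lapse/2 + (1 - lapse) * Phi((x - PSE) /
  sigma) on signed intensity (leftward negative).  The location is the
  point of subjective equality; shifts of the PSE quantify a bias to
  respond with the head's direction.

The super-subject analysis pools all participants' trials per rotation
condition before fitting, with percentile bootstrap confidence intervals
from trial-level resampling within condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import norm

__all__ = [
    "PsychometricFit",
    "fit_accuracy_pmf",
    "fit_directional_pmf",
    "predict_accuracy",
    "predict_right",
    "screen_staircase",
    "screen_condition",
    "build_threshold_table",
    "collapse_directions",
    "pool_super_subject",
    "bootstrap_super_subject",
]

_SLOPE_STARTS = (0.02, 0.05, 0.1, 0.2, 0.4)
_SLOPE_BOUNDS = (1e-4, 5.0)
_LOC_BOUNDS = (-1.5, 1.5)
_EPS = 1e-9


@dataclass(frozen=True)
class PsychometricFit:
    kind: Literal["accuracy", "directional"]
    location: float  # mu (accuracy threshold) or PSE
    slope: float
    fixed_guess: Optional[float]  # 0.5 for accuracy fits, None for directional
    fixed_lapse: float
    loglik: float
    n_trials: int
    converged: bool


def predict_accuracy(fit_or_mu, x, slope: float | None = None, lapse: float = 0.0):
    """Model-predicted P(correct) of the accuracy model."""
    if isinstance(fit_or_mu, PsychometricFit):
        mu, slope, lapse = fit_or_mu.location, fit_or_mu.slope, fit_or_mu.fixed_lapse
    else:
        mu = fit_or_mu
    return 0.5 + (0.5 - lapse) * norm.cdf((np.asarray(x, float) - mu) / slope)


def predict_right(fit: PsychometricFit, x):
    """Model-predicted P(respond right) of the directional model."""
    lam = fit.fixed_lapse
    return lam / 2 + (1 - lam) * norm.cdf((np.asarray(x, float) - fit.location) / fit.slope)


def _nll_factory(x: np.ndarray, y: np.ndarray, floor: float, span: float):
    """Negative Bernoulli log-likelihood for p = floor + span * Phi((x-loc)/s)."""

    def nll(theta):
        loc, log_s = theta
        p = floor + span * ndtr((x - loc) / math.exp(log_s))
        p = np.clip(p, _EPS, 1 - _EPS)
        return -(np.log(p[y]).sum() + np.log1p(-p[~y]).sum())

    return nll


def _ml_fit(
    x: np.ndarray,
    y: np.ndarray,
    floor: float,
    span: float,
    loc0: float,
    s0: float = 0.1,
    multistart: bool = True,
):
    """Maximize the Bernoulli likelihood over (location, slope).

    The slope is optimized on the log scale (positivity).  A heuristic
    start is tried first; the full multistart over slope seeds runs only
    if it fails or wanders to a bound.  Returns (loc, slope, loglik,
    converged).
    """
    nll = _nll_factory(x, y, floor, span)

    def solve(s0: float):
        return minimize(
            nll,
            np.array([loc0, math.log(s0)]),
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 300},
        )

    def admissible(res) -> bool:
        loc, log_s = res.x
        s = math.exp(log_s)
        return (
            res.success
            and _LOC_BOUNDS[0] < loc < _LOC_BOUNDS[1]
            and _SLOPE_BOUNDS[0] * 1.5 < s < _SLOPE_BOUNDS[1] / 1.5
        )

    best = solve(s0)
    if multistart and not admissible(best):
        results = [best] + [solve(s) for s in _SLOPE_STARTS]
        good = [r for r in results if admissible(r)]
        best = min(good or results, key=lambda r: r.fun)
    loc, log_s = best.x
    return float(loc), float(math.exp(log_s)), float(-best.fun), admissible(best)


def fit_accuracy_pmf(
    intensities: Sequence[float],
    correct: Sequence[bool],
    fixed_lapse: float = 0.0,
    min_trials: int = 20,
) -> PsychometricFit:
    """ML fit of the accuracy model to one participant-condition's trials
    (pooled over sessions).  The fitted location is the threshold: the
    75%-correct intensity when ``fixed_lapse`` is 0."""
    x = np.asarray(intensities, dtype=float)
    y = np.asarray(correct, dtype=bool)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("intensities and correct must be 1-D and equal length")
    if x.size < min_trials:
        raise ValueError(f"need at least {min_trials} trials, got {x.size}")
    if y.all() or not y.any():
        # separable data: the slope is unconstrained and the location
        # undefined; flag rather than report a spurious optimum
        return PsychometricFit(
            kind="accuracy", location=float(np.median(x)), slope=_SLOPE_BOUNDS[0],
            fixed_guess=0.5, fixed_lapse=fixed_lapse, loglik=float("nan"),
            n_trials=int(x.size), converged=False,
        )
    loc0 = float(np.median(x))
    loc, slope, ll, ok = _ml_fit(x, y, 0.5, 0.5 - fixed_lapse, loc0)
    return PsychometricFit(
        kind="accuracy",
        location=loc,
        slope=slope,
        fixed_guess=0.5,
        fixed_lapse=fixed_lapse,
        loglik=ll,
        n_trials=int(x.size),
        converged=ok,
    )


def fit_directional_pmf(
    signed_intensities: Sequence[float],
    responded_right: Sequence[bool],
    fixed_lapse: float = 0.01,
    start: tuple[float, float] | None = None,
    multistart: bool = True,
) -> PsychometricFit:
    """ML fit of the directional model; the location is the PSE on the
    signed-intensity axis (leftward negative).  ``start`` optionally warm
    starts the optimizer at a known (location, slope)."""
    x = np.asarray(signed_intensities, dtype=float)
    y = np.asarray(responded_right, dtype=bool)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D and equal length")
    if not ((x > 0).any() and (x < 0).any()):
        raise ValueError("directional fit needs trials on both sides of zero")
    loc0, s0 = start if start is not None else (0.0, 0.1)
    loc, slope, ll, ok = _ml_fit(
        x, y, fixed_lapse / 2, 1 - fixed_lapse, loc0, s0=s0, multistart=multistart
    )
    return PsychometricFit(
        kind="directional",
        location=loc,
        slope=slope,
        fixed_guess=None,
        fixed_lapse=fixed_lapse,
        loglik=ll,
        n_trials=int(x.size),
        converged=ok,
    )


def screen_staircase(
    trace: pd.DataFrame,
    intensity_ceiling: float = 1.0,
    last_n: int = 20,
    min_accuracy: float = 0.50,
) -> str:
    """Keep/drop screen for one session's staircase in one condition.

    Drops a trace whose final estimate sits at (>= 95% of) the intensity
    ceiling -- the staircase railed because the criterion level was out of
    reach -- or whose accuracy over the last ``last_n`` trials fell below
    ``min_accuracy``, an automated stand-in for visual inspection of
    staircase convergence.  The accuracy cut sits at chance rather than
    closer to the 75% target: a staircase tracking 75% shows binomial
    fluctuation of its trailing accuracy, and a stricter cut falsely drops
    several percent of well-converged runs per condition.
    """
    if len(trace) == 0:
        raise ValueError("empty staircase trace")
    final = float(trace["estimate"].iloc[-1])
    if final >= 0.95 * intensity_ceiling:
        return "drop"
    tail = trace["correct"].iloc[-last_n:]
    if tail.mean() < min_accuracy:
        return "drop"
    return "keep"


def screen_condition(traces: Iterable[pd.DataFrame], intensity_ceiling: float = 1.0) -> str:
    """A condition survives only if every session's staircase passes."""
    verdicts = [screen_staircase(t, intensity_ceiling) for t in traces]
    if not verdicts:
        raise ValueError("no traces supplied")
    return "keep" if all(v == "keep" for v in verdicts) else "drop"


def build_threshold_table(
    trials: pd.DataFrame,
    traces: Dict[str, Dict[tuple, pd.DataFrame]],
    fixed_lapse: float = 0.0,
    intensity_ceiling: float = 1.0,
    min_trials: int = 20,
) -> pd.DataFrame:
    """One row per participant x (direction x rotation) cell.

    Each cell's staircases are screened (both sessions must pass); kept
    cells pool trials across sessions and fit the accuracy model.  Cells
    that are dropped or fail to converge are flagged ``excluded`` and carry
    no threshold.
    """
    rows = []
    for pid, sub in trials.groupby("participant", sort=True):
        ptraces = traces.get(pid, {})
        for (d, r), cell in sub.groupby(["stim_direction", "head_rotation"], sort=True):
            cell_traces = [
                ptraces[k] for k in sorted(ptraces) if k[1] == d and k[2] == r
            ]
            congruence = cell["congruence"].iloc[0]
            row = {
                "participant": pid,
                "stim_direction": d,
                "head_rotation": r,
                "congruence": congruence,
                "threshold": np.nan,
                "slope": np.nan,
                "excluded": True,
                "n_trials": int(len(cell)),
            }
            keep = bool(cell_traces) and screen_condition(cell_traces, intensity_ceiling) == "keep"
            if keep and len(cell) >= min_trials:
                fit = fit_accuracy_pmf(
                    cell["presented_intensity"], cell["correct"],
                    fixed_lapse=fixed_lapse, min_trials=min_trials,
                )
                if fit.converged and 0 < fit.location <= intensity_ceiling:
                    row.update(threshold=fit.location, slope=fit.slope, excluded=False)
            rows.append(row)
    return pd.DataFrame(rows)


def collapse_directions(table: pd.DataFrame) -> pd.DataFrame:
    """Mean threshold per participant x congruence, collapsing the left
    and right stimulus-direction cells (excluded cells dropped)."""
    kept = table.loc[~table["excluded"]]
    out = (
        kept.groupby(["participant", "congruence"], sort=True)["threshold"]
        .mean()
        .reset_index()
    )
    return out


def pool_super_subject(
    trials: pd.DataFrame, fixed_lapse: float = 0.01
) -> Dict[str, PsychometricFit]:
    """Directional fit per head-rotation condition on trials pooled across
    all participants (the super subject)."""
    if trials["participant"].nunique() < 1 or len(trials) == 0:
        raise ValueError("no trials to pool")
    fits = {}
    for rot, grp in trials.groupby("head_rotation", sort=True):
        if len(grp) == 0:
            raise ValueError(f"empty condition {rot!r}")
        fits[rot] = fit_directional_pmf(
            grp["signed_intensity"], grp["response"] == "right", fixed_lapse=fixed_lapse
        )
    return fits


def bootstrap_super_subject(
    trials: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    fixed_lapse: float = 0.01,
) -> pd.DataFrame:
    """Percentile bootstrap of the super-subject PSE per rotation condition.

    Trials are resampled with replacement within each condition, the
    directional model refitted per replicate; returns the point estimate,
    bootstrap mean and 2.5/97.5 percentile CI per condition.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    rng = np.random.default_rng(seed)
    rows = []
    for rot in sorted(trials["head_rotation"].unique()):
        grp = trials.loc[trials["head_rotation"] == rot]
        n = len(grp)
        if n < 10:
            raise ValueError(f"condition {rot!r} has fewer than 10 trials")
        x = grp["signed_intensity"].to_numpy(float)
        y = (grp["response"] == "right").to_numpy()
        point = fit_directional_pmf(x, y, fixed_lapse=fixed_lapse)
        warm = (point.location, point.slope)
        pses = np.empty(B)
        for b in range(B):
            idx = rng.integers(0, n, size=n)
            xb, yb = x[idx], y[idx]
            if not ((xb > 0).any() and (xb < 0).any()):
                idx = rng.integers(0, n, size=n)
                xb, yb = x[idx], y[idx]
            fit = fit_directional_pmf(
                xb, yb, fixed_lapse=fixed_lapse, start=warm, multistart=False
            )
            pses[b] = fit.location
        lo, hi = np.percentile(pses, [2.5, 97.5])
        rows.append(
            {
                "head_rotation": rot,
                "pse": point.location,
                "pse_boot_mean": float(pses.mean()),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "n_trials": n,
                "B": B,
            }
        )
    return pd.DataFrame(rows)
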