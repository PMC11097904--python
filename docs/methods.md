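# Methods

This note documents the models implemented in `rotovis`, the defaults and
why they were chosen, what the synthetic observers do and do not emulate,
and the numerical choices that matter.

## The paradigm being simulated

An observer wearing a head-mounted display judges a briefly presented
(400 ms) drifting luminance pattern while either keeping the head still or
rotating it left/right behind a 40°/s motion guide. The pattern is
head-locked, so retinal drift speed is fixed regardless of head motion.
Two task variants exist: a *direction* task (report left/right drift; the
six cells cross 2 stimulus directions × 3 head rotations) and a *detection*
task (the pattern's motion is confined to the upper or lower half; report
which). Signal strength is controlled per condition by an adaptive
staircase holding performance at 75% correct; the dependent measure is the
75%-correct signal intensity from a psychometric fit.

## Stimulus (LSNR construction)

Each frame is the per-pixel average of a *signal* field, shifted laterally
by `shift_px` each motion update, and a *noise* field redrawn at every
update (synchronous refresh, so the two fields cannot be segregated
temporally). Pixel luminances are drawn from a normal distribution
truncated to [0, 1] (mean 0.5, SD 0.25) — the truncation preserves a
bounded display range while keeping a Gaussian black-and-white texture;
clipping or rescaling would distort the contrast-energy bookkeeping.
Field contrasts are scaled about mid-grey with
`contrast_noise = sqrt(1 − contrast_signal²)`, so the variance of the
average is independent of signal level: motion strength changes, mean and
RMS contrast do not (audited to within 2% in tests).

Geometry defaults: 15.22° square aperture, 120 px pattern, 90 Hz display,
400 ms (36 frames). A nominal 7.62°/s drift with a 2 px shift per update
forces a 30 Hz update rate (every third display frame). The pixel pitch is
rounded to 0.127°/px so that the realised speed of integer 2 px shifts is
exactly the nominal 7.62°/s; the `StimulusSpec` records the realised speed as
`actual_drift_speed_deg`. The signal field wraps toroidally (avoids
aperture-edge density artifacts). In hemifield mode the motion/noise
process runs in one half of the patch and the other half is rendered once
from the same mixture and frozen — a stationary pattern of matched
contrast with zero frame-to-frame motion energy.

`measure_drift_speed` is the package's own verification oracle: circular
cross-correlation between consecutive updates, exact for pure-signal
stacks because displacement is an integer number of pixels.

## Trial schedules

30 trials per (direction × rotation) cell per block, two blocks, orders
shuffled uniformly and independently per block under a seed; the detection
variant splits every cell equally between upper and lower placement.
Stimulus onset is 1.2 s from guide entry in the direction task and 2.2 s
in the detection task (guide arrival is at 1 s; the later onset puts the
stimulus inside the constant-velocity plateau — visible in the simulated
kinematics, where the 1.2 s onset still overlaps the acceleration ramp).
Blocks and "sessions" are treated as synonyms; one scheduling code path.
The 900 ms inter-trial interval is carried in the schedule but unused by
analysis. Randomization is unconstrained (no run-length limits).

## Adaptive staircase

A QUEST-style grid posterior over log10 threshold: grid −3…0 in 0.005
steps, assumed Weibull with slope 3.5, guess 0.5, lapse 0.01 — the
procedure's conventional defaults; nothing in the paradigm pins them, and
the estimate is insensitive to grid refinement (≤1e−3 at half the step).
The assumed function is shifted so the threshold parameter marks the
75% point, making placements (posterior mean, clamped to [0.001, 1]) land
where the observer is expected to be 75% correct and the final estimate
directly interpretable as the 75%-correct intensity. Simulations show the
mean true accuracy at the final 60-trial estimate is ~75.5–76%, slightly
above target: placement mean-reversion under a proper prior plus the
Weibull/Gaussian mismatch leave a fraction-of-a-point conservative bias,
well inside the ±3-point calibration band, and robust to a misplaced
prior. Updates are functional (each returns a new state), so any
posterior equals the one-shot product of prior and per-trial likelihoods —
an identity the tests check to 1e−10. Posterior-mode placement is
available via config but off by default; quantile placement is not
implemented.

## Synthetic observers

Each participant carries per-condition thresholds `μ_c` on the [0, 1]
intensity scale, a slope `σ`, a lapse rate, a head-direction criterion
bias `δ`, and head-speed parameters.

*Detection model* (hemifield task):
`P(correct | x) = 0.5 + (0.5 − λ)·Φ((x − μ_c)/σ)` — chance at zero signal,
75% at `μ_c` when `λ = 0`.

*Direction model*: `P(right | x) = λ/2 + (1 − λ)·Φ((x + δ·h)/σ_c)` with
`h ∈ {−1, 0, +1}` the head direction. The bias is implemented as a
criterion (PSE) shift — additive in signed intensity — because that is how
the super-subject analysis quantifies it; a multiplicative-gain mechanism
would be observationally similar near threshold and is out of scope. The
per-condition slope is derived from the condition threshold,
`σ_c = μ_c / Φ⁻¹((0.75 − λ/2)/(1 − λ))`, so that absent bias the direction
task's 75%-correct point is exactly `μ_c`. Correctness is judged against
the true stimulus direction, so the bias *helps* congruent trials and
*hurts* incongruent ones: the measured thresholds shift to `μ_c − δ` and
`μ_c + δ` respectively. This deliberately reproduces the confound the
paradigm cannot internally resolve (perceptual vs decisional origin of the
bias); the generator implements one mechanism and labels it as such.

Default populations (chosen once, from the reported group effects, and
used as the study conditions throughout):

* direction task: `μ = 0.30 / 0.33 / 0.36` (stationary / congruent /
  incongruent) with `δ = 0.10`, so the *measured* condition effects are
  ≈ −0.07 (congruent − stationary) and ≈ +0.16 (incongruent − stationary);
* detection task: `μ = 0.25 / 0.30 / 0.30`, `δ` irrelevant to accuracy
  (the upper/lower response removes the left/right criterion overlap).

Between-participant variability: a shared log-normal participant scale
factor on all `μ_c` (CV 20% — the random intercept the mixed models
assume) plus independent log-normal condition jitter (CV 3%; condition
effects within a participant are far more stable than overall
sensitivity); slope and bias CV 20%; lapse fixed at 0.02.

*Head kinematics*: trapezoidal yaw-velocity profile — zero until guide
arrival (1 s) plus a 50 ms onset latency, a 0.3 s linear ramp to a
per-trial plateau drawn from Normal(38, 2) °/s (slightly slower than the
40°/s guide), held through stimulus offset, with 0.5 °/s velocity jitter
throughout; stationary trials are jitter only. The velocity trace is
signed by the commanded direction, so mirrored commands under the same RNG
state give exact mirror trajectories. The return-to-centre movement is not
simulated (the analysis window ends at stimulus offset), so "whole
rotation" speed averages are diluted by the ramp but not by deceleration.

What the generator does **not** emulate: eye movements and fixation error,
vestibular transduction noise, reaction times, learning/fatigue across
blocks, 3D arc geometry of the guide (yaw only), and any perceptual (as
opposed to criterion) origin of the bias. Passing tests therefore show the
*analysis chain* is correct and calibrated under the stated response
models — not that those models exhaust real observers.

## Psychometric estimation

Staircase traces are screened per session: drop if the final estimate
railed at ≥95% of the intensity ceiling (criterion level out of reach) or
trailing-20-trial accuracy fell below 0.50. The accuracy cut sits at
chance rather than nearer the 75% target because a staircase tracking 75%
shows binomial fluctuation in any 20-trial window; a 0.60 cut falsely
drops ~4% of well-converged runs per trace, which compounds to ~40% of
participants losing at least one of six cells. Both sessions must pass for
a condition to survive; kept cells pool sessions (≥20 trials) and fit the
accuracy model by maximum likelihood — Nelder–Mead on (location,
log-slope), heuristic start at the median intensity with a 5-point slope
multistart fallback, and a separable-data guard (all-correct or
all-incorrect responses are flagged non-converged rather than fitted).
The lapse is fixed at 0 for accuracy fits — making `μ̂` exactly the
75% point — and at 0.01 for directional fits (a free lapse is unstable at
60 trials/cell); both are configurable.

The super-subject analysis concatenates all participants' trials per
rotation condition and fits the directional model; uncertainty comes from
a percentile bootstrap with trial-level resampling within condition
(B=1000 by default; bootstrap refits warm-start at the point fit).
Participant-level resampling is the obvious alternative reading of "full
resampling"; trial-level was chosen as the finer-grained unit and the
participant-level variant can be composed from `pool_super_subject` on
resampled cohorts. Percentile CIs (rather than BCa) match the reported
simplicity; their coverage is verified at 93–97% nominal on 360-trial
replicates — they undercover slightly at much smaller sizes, which is a
property of percentile intervals, not of this implementation.

## Group inference

The 2×3 repeated-measures ANOVA (via `pingouin`) uses listwise deletion —
only participants with all six cells — with uncorrected dfs (no sphericity
correction by default, matching the reporting style; partial
η² = SS_e/(SS_e+SS_err) is recovered from F and the dfs). Post-hocs are
paired t-tests on direction-collapsed thresholds, Bonferroni ×3, with
paired (difference-score) Cohen's d. The mixed-model comparison
(`statsmodels` MixedLM, maximum likelihood, not REML) fits the nested
sequence intercept-only → +congruence → +direction → +interaction, all
with a random intercept per participant and *all available cells* (no
listwise deletion — the two analyses intentionally run on different
effective samples, as their dfs make explicit). Adjacent models are
compared by likelihood-ratio tests; the winning model is the last one that
significantly improved on its predecessor, and its treatment-coded
coefficients (reference: stationary) are reported with normal-based 95%
CIs, t statistics on residual df (n_obs − k_fixed), and the
incongruent-vs-congruent contrast. Boundary/singular random-effect fits
are flagged but still reported.

Head-speed summaries compute per-trial speed as |Δyaw|/Δt from guide
arrival to stimulus offset (means sit below the plateau because of the
ramp — by construction), per-participant means and within-trial SDs, and a
compliance flag (stimulus-window speed < 10°/s on rotation trials or
> 10°/s when stationary). Speed–threshold regressions are per-direction
OLS with adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2).

## Validation suite: problem sizes

The package's calibration claims are each tied to a simulation in the test
suite, at sizes chosen to balance statistical resolution against a desk-
scale run: staircase convergence over 200 replicate 60-trial runs
(75% ± 3 points); threshold recovery over 100 closed-loop
participant-conditions of 600 trials (median |μ̂ − μ| ≤ 0.02, sign test);
bias recovery and CI behaviour on cohorts of 20 with B=200; type-I
calibration of the full cohort→screen→fit→ANOVA chain over 500 null
replicates at n=10 with 15 trials/cell/block (rejection 0.05 ± 0.02,
computed over analyzable replicates — a few percent fall below 3 complete
cases and cannot be tested); and qualitative pattern reproduction over 50
cohorts of 20 per task variant (≥80% post-hoc pattern match). The null
PSE check runs over ten cohorts (30 CIs) because a joint assertion on one
cohort's three 95% intervals fails ~14% of the time even for a perfectly
calibrated method.

## Known limitations

* The bias is purely decisional in the generator; real data cannot be
  used to distinguish this from a perceptual gain mechanism, and neither
  can this package.
* Accuracy-fit thresholds on the direction task conflate sensitivity and
  bias by design; `recover_parameters` therefore scores estimates against
  bias-adjusted expected values (`μ_c ∓ δ`), not raw `μ_c`.
* MixedLM coefficient dfs use the residual-df convention; Satterthwaite or
  Kenward–Roger corrections are not implemented.
* The staircase's assumed Weibull slope is fixed; severely mismatched
  observer slopes will converge more slowly (though the 75% calibration is
  robust in the tested range).
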