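"""Luminance signal-to-noise ratio (LSNR) motion stimulus.

The stimulus thresholded throughout the package is a square patch of random
luminance pixels in which a drifting "signal" field is mixed with a
synchronously refreshed static "noise" field.  Signal strength is the
contrast allotted to the drifting field; the noise field's contrast is set
so that total contrast energy is constant::

    contrast_noise = sqrt(1 - contrast_signal**2)

so varying the signal level changes motion strength without changing the
mean or RMS contrast of the patch.  Each presentation frame is the
per-pixel average of the two contrast-scaled fields; the noise field is
redrawn at every motion update so the two fields cannot be segregated by
their temporal signatures.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StimulusSpec",
    "FrameStack",
    "exp1_spec",
    "exp2_spec",
    "noise_contrast_for_signal",
    "synthesize_frames",
    "measure_drift_speed",
    "audit_mean_contrast",
    "save_frames",
]

HemifieldMode = Literal["off", "upper", "lower"]

# Pixel luminances are drawn from a normal distribution truncated to [0, 1]
# (mean 0.5, SD 0.25): bounded like a display while keeping the gaussian
# "black and white noise" texture.
_TRUNC_LO, _TRUNC_HI = 0.0, 1.0
_PIX_MEAN, _PIX_SD = 0.5, 0.25


@dataclass(frozen=True)
class StimulusSpec:
    """Geometry and timing of the motion patch.

    The defaults correspond to the direction-judgement experiment: a
    15.22 degree square aperture holding a 120 px pattern drifting at a
    nominal 7.62 deg/s on a 90 Hz display.  Signal pixels shift
    ``shift_px`` per motion update; with 2 px per update the nominal speed
    forces a 30 Hz update rate (every third display frame).
    """

    aperture_deg: float = 15.22
    pattern_px: int = 120
    drift_speed_deg: float = 7.62
    display_hz: float = 90.0
    motion_update_hz: float = 30.0
    shift_px: int = 2
    duration_s: float = 0.4
    hemifield_mode: HemifieldMode = "off"

    def __post_init__(self) -> None:
        if self.aperture_deg <= 0:
            raise ValueError("aperture_deg must be positive")
        if self.pattern_px < 2:
            raise ValueError("pattern_px must be at least 2")
        if not (0 < self.motion_update_hz <= self.display_hz):
            raise ValueError("motion_update_hz must lie in (0, display_hz]")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.shift_px < 1:
            raise ValueError("shift_px must be at least 1")
        if self.hemifield_mode not in ("off", "upper", "lower"):
            raise ValueError(f"unknown hemifield_mode {self.hemifield_mode!r}")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.display_hz))

    @property
    def frames_per_update(self) -> int:
        return int(round(self.display_hz / self.motion_update_hz))

    @property
    def n_updates(self) -> int:
        return math.ceil(self.n_frames / self.frames_per_update)

    @property
    def deg_per_px(self) -> float:
        """Pixel pitch in degrees, rounded to 3 decimals.

        Rounding makes the realised drift speed (shift_px * update rate *
        pitch) land exactly on the nominal speed for the default geometry.
        """
        return round(self.aperture_deg / self.pattern_px, 3)

    @property
    def actual_drift_speed_deg(self) -> float:
        """Drift speed actually realised by integer pixel shifts (deg/s)."""
        return self.shift_px * self.motion_update_hz * self.deg_per_px


def exp1_spec(**overrides) -> StimulusSpec:
    """Spec for the full-field direction-judgement stimulus."""
    return StimulusSpec(**overrides)


def exp2_spec(hemifield_mode: HemifieldMode = "upper", **overrides) -> StimulusSpec:
    """Spec for the hemifield detection stimulus (10 degree aperture)."""
    overrides.setdefault("aperture_deg", 10.0)
    return StimulusSpec(hemifield_mode=hemifield_mode, **overrides)


@dataclass(frozen=True)
class FrameStack:
    """Rendered stimulus: frames are 2-D luminance arrays in [0, 1]."""

    frames: np.ndarray  # (n_frames, pattern_px, pattern_px)
    spec: StimulusSpec
    signal_contrast: float
    direction: Literal["left", "right"]
    seed: int

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")

    @property
    def update_frames(self) -> np.ndarray:
        """One frame per motion update (the first frame of each hold)."""
        return self.frames[:: self.spec.frames_per_update]


def noise_contrast_for_signal(signal_contrast: float) -> float:
    """Noise-field contrast that keeps total contrast energy constant.

    Returns ``sqrt(1 - signal_contrast**2)`` so that
    ``signal**2 + noise**2 == 1``.
    """
    c = float(signal_contrast)
    if not (0.0 <= c <= 1.0):
        raise ValueError(f"signal_contrast must be in [0, 1], got {c}")
    return math.sqrt(1.0 - c * c)


def _draw_field(rng: np.random.Generator, n: int) -> np.ndarray:
    a = (_TRUNC_LO - _PIX_MEAN) / _PIX_SD
    b = (_TRUNC_HI - _PIX_MEAN) / _PIX_SD
    return sps.truncnorm.rvs(
        a, b, loc=_PIX_MEAN, scale=_PIX_SD, size=(n, n), random_state=rng
    )


def _scale_contrast(field_: np.ndarray, contrast: float) -> np.ndarray:
    return 0.5 + contrast * (field_ - 0.5)


def synthesize_frames(
    spec: StimulusSpec,
    signal_contrast: float,
    direction: Literal["left", "right"],
    seed: int,
) -> FrameStack:
    """Render the LSNR stimulus.

    The signal field shifts ``spec.shift_px`` pixels per motion update in
    ``direction`` with toroidal wrap; an independent noise field is redrawn
    at each update.  Each output frame is the per-pixel average of the
    contrast-scaled signal and noise fields; frames within a motion update
    are identical (held for ``frames_per_update`` display frames).

    In hemifield mode the motion/noise process runs in one half of the
    patch only; the other half is rendered once from the same mixture and
    frozen across updates (a stationary pattern of matched contrast).
    """
    if direction not in ("left", "right"):
        raise ValueError(f"direction must be 'left' or 'right', got {direction!r}")
    c_sig = float(signal_contrast)
    c_noise = noise_contrast_for_signal(c_sig)  # validates range
    rng = np.random.default_rng(seed)
    n = spec.pattern_px
    sign = 1 if direction == "right" else -1

    signal_field = _draw_field(rng, n)
    half = n // 2
    rows = {
        "off": slice(0, n),
        "upper": slice(0, half),
        "lower": slice(half, n),
    }[spec.hemifield_mode]

    static_half = None
    updates = np.empty((spec.n_updates, n, n))
    for u in range(spec.n_updates):
        shifted = np.roll(signal_field, sign * spec.shift_px * u, axis=1)
        noise_field = _draw_field(rng, n)
        mixed = 0.5 * (
            _scale_contrast(shifted, c_sig) + _scale_contrast(noise_field, c_noise)
        )
        if spec.hemifield_mode == "off":
            updates[u] = mixed
        else:
            if static_half is None:
                static_half = mixed.copy()
            updates[u] = static_half
            updates[u, rows, :] = mixed[rows, :]

    frames = np.repeat(updates, spec.frames_per_update, axis=0)[: spec.n_frames]
    return FrameStack(
        frames=frames,
        spec=spec,
        signal_contrast=c_sig,
        direction=direction,
        seed=int(seed),
    )


def _best_shift(prev: np.ndarray, curr: np.ndarray) -> int:
    """Signed horizontal displacement (px, rightward positive) maximizing
    the circular cross-correlation between two frames."""
    a = prev - prev.mean()
    b = curr - curr.mean()
    fa = np.fft.rfft(a, axis=1)
    fb = np.fft.rfft(b, axis=1)
    corr = np.fft.irfft(np.conj(fa) * fb, n=a.shape[1], axis=1).sum(axis=0)
    k = int(np.argmax(corr))
    w = a.shape[1]
    return k - w if k > w // 2 else k


def measure_drift_speed(stack: FrameStack) -> float:
    """Estimate net horizontal drift (deg/s, rightward positive).

    Cross-correlates consecutive motion updates to find the displacement
    per update and converts to deg/s with the pixel pitch of the stack's
    StimulusSpec.  On a
    pure-signal stack this recovers the configured speed exactly because
    displacement is an integer number of pixels per update.
    """
    spec = stack.spec
    keyframes = stack.update_frames
    if keyframes.shape[0] < 2:
        raise ValueError("need at least 2 motion updates to measure drift")
    half = spec.pattern_px // 2
    rows = {
        "off": slice(0, spec.pattern_px),
        "upper": slice(0, half),
        "lower": slice(half, spec.pattern_px),
    }[spec.hemifield_mode]
    shifts = [
        _best_shift(keyframes[i, rows, :], keyframes[i + 1, rows, :])
        for i in range(keyframes.shape[0] - 1)
    ]
    px_per_update = float(np.mean(shifts))
    return px_per_update * spec.motion_update_hz * spec.deg_per_px


def audit_mean_contrast(stacks: Sequence[FrameStack]) -> pd.DataFrame:
    """Grand mean and RMS contrast of each stack.

    All stacks must share a spec.  The LSNR construction keeps RMS
    contrast constant across signal levels (max pairwise difference below
    2% of the mean RMS); this audit exposes the per-stack numbers so that
    contract can be checked.
    """
    stacks = list(stacks)
    if not stacks:
        raise ValueError("no stacks to audit")
    spec0 = stacks[0].spec
    for s in stacks[1:]:
        if s.spec != spec0:
            raise ValueError("all stacks must share the same StimulusSpec")
    rows = [
        {
            "signal_contrast": s.signal_contrast,
            "mean": float(s.frames.mean()),
            "rms_contrast": float(s.frames.std()),
        }
        for s in stacks
    ]
    return pd.DataFrame(rows)


def save_frames(stack: FrameStack, outdir: str | Path) -> Path:
    """Write the stack as 8-bit grayscale PNGs plus a JSON sidecar."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(stack.frames):
        iio.imwrite(
            outdir / f"frame_{i:04d}.png",
            np.clip(frame * 255, 0, 255).astype(np.uint8),
        )
    meta = {
        "spec": asdict(stack.spec),
        "signal_contrast": stack.signal_contrast,
        "direction": stack.direction,
        "seed": stack.seed,
        "n_frames": int(stack.frames.shape[0]),
        "actual_drift_speed_deg": stack.spec.actual_drift_speed_deg,
    }
    (outdir / "stimulus.json").write_text(json.dumps(meta, indent=2))
    return outdir
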