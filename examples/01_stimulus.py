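"""Render the LSNR motion stimulus and audit its contracts.

Builds the full-field direction-task stimulus at three signal levels,
measures the realised drift speed with the cross-correlation oracle, and
shows that RMS contrast stays constant while signal strength varies --
the defining property of the luminance signal-to-noise construction.
"""

from rotovis import (
    audit_mean_contrast,
    exp1_spec,
    measure_drift_speed,
    noise_contrast_for_signal,
    synthesize_frames,
)

spec = exp1_spec()
print(f"spec: {spec.n_frames} frames, {spec.pattern_px} px pattern, "
      f"drift {spec.actual_drift_speed_deg:.2f} deg/s "
      f"({spec.shift_px} px per update at {spec.motion_update_hz:.0f} Hz)")

for c in (0.0, 0.5, 1.0):
    print(f"signal contrast {c:.1f} -> noise contrast "
          f"{noise_contrast_for_signal(c):.3f} (energy constant)")

stacks = [synthesize_frames(spec, c, "right", seed=1) for c in (0.0, 0.5, 1.0)]
print(audit_mean_contrast(stacks).round(4).to_string(index=False))
print("-> mean and RMS contrast barely move while motion strength spans 0..1")

pure = synthesize_frames(spec, 1.0, "left", seed=7)
print(f"measured drift of a pure-signal leftward stack: "
      f"{measure_drift_speed(pure):+.2f} deg/s (configured -7.62)")
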