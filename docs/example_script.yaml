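# Example posture script for `dualact simulate`.
# A short ward-style scenario: mostly lying, a seated spell, a brief stand
# and a short walk. Durations in seconds; enmo_target in mg.
seed: 42
jitter_sd: 5.0            # per-segment orientation jitter (deg)
roll_sd: 15.0             # per-segment roll about the device x axis (deg)
mounting_offset_lowerleg: 8.0   # constant strap misalignment (deg)
machine_noise_sd: 2.0     # >20 Hz sensor noise (mg)
miscalibration:
  offset: [0.02, -0.01, 0.015]  # g
  gain: [1.01, 0.99, 1.005]
segments:
  - {posture: lying, duration: 600}
  - {posture: sitting, duration: 300}
  - {posture: standing, duration: 30}
  - {posture: moving, duration: 60, enmo_target: 25}
  - {posture: sitting, duration: 120}
  - {posture: lying, duration: 300}
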