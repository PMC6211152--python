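# Methods

## Measurement model

Two tri-axial accelerometers are worn on the thigh and the lower leg, each
sampling at ~100 Hz in g units, x axis along the limb pointing toward the
feet. When a sensor is still it measures only the gravity reaction, so the
orientation of the limb is recoverable from the direction of the measured
vector and movement from deviations of its magnitude from 1 g. The pipeline
assumes continuous wear (devices fitted and removed by staff), so no
nonwear detection is performed, and a fixed, regular sampling rate —
irregular streams are rejected (tolerance 1% on inter-sample intervals)
rather than resampled, since any resampling policy would be an invention.

Processing order: autocalibration → 20 Hz low-pass → sample-level ENMO and
pitch → 5-s epoch means → lower-leg mounting correction → classification.

## Autocalibration

Per-axis offset `o` and gain `g` are estimated so that still-period vectors
have unit norm, minimising Σ(‖g⊙v + o‖ − 1)² by Gauss–Newton from the
identity, stopping when the mean absolute residual improves by < 1e-9 g or
after 1000 iterations. Still periods are non-overlapping 10-s windows whose
per-axis SD is below 13 mg; both parameters are configurable
(`calibration_window`, `calibration_still_sd`). The fit is pooled across all
data from one device rather than per record, since ward wear gives short
records with few distinct orientations.

Thigh/shank wear can still leave the sampled orientations nearly collinear,
which makes the six-parameter fit unidentifiable. If all still directions
lie within 30° of their mean direction, the fit falls back to offset-only
and is flagged `converged=False`; fits with gain outside [0.8, 1.2] or
offset outside ±0.25 g are likewise flagged. Fewer than two still windows
raises an error and the pipeline falls back to identity calibration with a
logged warning. Temperature terms and within-record drift are not modelled.

## Signals and epochs

* ENMO is truncated **per sample** before averaging, so a motionless,
  perfectly calibrated epoch is exactly 0 mg regardless of orientation.
* Pitch is `atan2(x, √(y²+z²))` in degrees; `y = z = 0` resolves to ±90 by
  the sign of x, the zero vector is an error. Epoch pitch is the mean of
  per-sample pitches (not the pitch of the mean vector): with the signal
  already low-passed the two differ negligibly in still epochs, and the
  per-sample mean is the simpler contract to verify.
* The low-pass is a 4th-order Butterworth applied in a single forward pass
  per axis. A single pass (rather than zero-phase forward-backward) keeps
  the empirical −3 dB point exactly at the configured cutoff, which makes
  the filter contract directly measurable by a sinusoid sweep; the group
  delay (~10 ms at 100 Hz) is far below the 5-s epoch scale.
* Epochs tile the record from its start; a trailing partial epoch is
  dropped. The two sensors' epoch grids are aligned on the later-starting
  series, pairing nearest epoch starts within half an epoch; clock drift
  beyond start-time alignment is out of scope.

## Mounting correction and classification

The shank sensor's case is strapped at an unknown constant angle to the
bone. Since every wearer is assumed to have walked at least once — bringing
the shank through vertical — the record's minimum lower-leg epoch pitch is
treated as a −90° calibration point: all lower-leg pitches are reduced by
`min(θ_L) + 90`. The offset is computed from epoch-level means, not
sample-level minima, which are noise-dominated. The corrected minimum is
−90.0 exactly (the subtraction is arranged as `(θ − min) − 90` so floating
point cannot smear the anchor) and the operation is idempotent. If no epoch
shows an upright thigh (θ_T ≤ −45°) the walking assumption is dubious; the
correction is still applied but a warning is emitted and recorded in the
run manifest. No symmetric correction is applied to the thigh sensor: the
thigh never reliably visits a known orientation, and the classification
thresholds leave ≥ 40° of margin to strap error.

Classification checks the shank first: a horizontal shank (θ_L > −45°)
means the legs are not weight-bearing and the epoch is lying, regardless of
thigh angle — this makes the rule branches exhaustive and mutually
exclusive and sends the physically incompatible vertical-thigh /
horizontal-shank combination to lying. The 45° threshold is the symmetric
midpoint between the horizontal (0°) and vertical (−90°) segment
prototypes; it is configurable (`upright_angle_threshold`). Movement is
tested only within the standing branch, from the lower-leg epoch ENMO with
a strict `> 13 mg` cut-off (`enmo_moving_threshold`).

Sign convention: "upright" reads **−90°**, consistent with the correction
anchor. Summaries report the percentage of classified epochs per label
(summing to 100) and total hours; the timeline export is a run-length
encoding of the label sequence for plotting in notebooks.

## Synthetic recordings

The generator emulates the study conditions so that every stage has a
ground truth: gravity-dominated signals at posture-prototype orientations
(pitch of thigh/shank: lying 0/0°, sitting 0/−75°, standing −85/−85°,
moving −85/−90°), movement bursts, >20 Hz machine noise, per-axis
miscalibration applied as the exact inverse of the calibration map, and a
constant lower-leg mounting misalignment. Standing sits 5° off vertical, as
real limbs do, so threshold robustness is exercised; during walking the
shank swings about the vertical, so the *moving* prototype's epoch-mean
shank pitch is −90° — this is what makes the record's minimum pitch a valid
anchor for the mounting correction, mirroring the walking assumption.
Mounting-offset recovery within 1° therefore requires the script to contain
a moving segment; a record whose most upright posture is the −85° standing
prototype would bias the recovered offset by those 5°, exactly as a real
patient who never walked would.

Movement is a 2 Hz sinusoidal acceleration burst with random phase directed
along the instantaneous gravity axis: a gravity-parallel burst changes the
vector norm but not its direction, so pitch is untouched and the movement
and posture channels stay independent. Its amplitude is solved by
root-finding so the expected truncated-ENMO epoch mean equals the segment
target (default 25 mg — comfortably above the 13 mg cut-off and of the
order measured on a shank during very slow gait, where ~16 mg is typical at
0.1 m/s against ~4 mg stationary).

Orientation realism: per-segment pitch jitter ~ N(0, jitter_sd²) held
within the segment plus a small per-sample tremor (SD = jitter_sd/20, small
enough that still-window detection survives), and a per-segment roll angle
~ N(0, roll_sd², default 15°) about the x axis. Roll changes neither pitch
nor ENMO but moves still orientations off a single plane, which is what
makes the six-parameter calibration identifiable from posture prototypes
that are otherwise coplanar. Everything is deterministic given the script
seed.

What the generator does **not** model: biomechanically detailed gait,
pressure-relieving-mattress artifacts, postural transitions (orientation
steps are instantaneous), device clock drift, temperature effects. Passing
closure tests on synthetic data therefore demonstrates the pipeline's
internal consistency — that each stage inverts the corresponding injected
distortion — not clinical validity on patients.

## Problem sizes and numerical choices

Tests and the acceptance script use short recordings (tens of seconds to
~10 minutes at 100 Hz); every stage is linear in sample count, so behaviour
is identical on multi-day records. Closure tests use a 500-s four-posture
script (ground truth 60/30/6/4%) noiseless, and a 380-s non-epoch-aligned
script with 5° jitter and 2 mg machine noise; calibration recovery uses 50
random orientations with 2 mg noise against injected 50 mg / 2% errors. The
filter's −3 dB point is located empirically by a 10–30 Hz sweep in 0.5 Hz
steps with steady-state RMS amplitudes (first 2 s discarded) and linear
interpolation at gain 1/√2.

Degenerate inputs: records shorter than one epoch, empty frames, zero
acceleration vectors, non-finite classifier inputs and cutoffs at or above
Nyquist all raise typed errors; an epoch ENMO of exactly 13 mg is standing
(the cut-off is strictly greater-than).
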