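"""Ground-truth two-sensor recording generator.

A posture script is an ordered list of (posture, duration) segments; each
posture has a prototype orientation for the two sensors, expressed as the
pitch of the device x axis (x points toward the feet, so upright reads
near -90 deg):

====================  ===========  ==============
posture               thigh pitch  lower-leg pitch
====================  ===========  ==============
lying                   0 deg         0 deg
sitting                 0 deg       -75 deg
standing              -85 deg       -85 deg
moving (upright)      -85 deg       -90 deg
====================  ===========  ==============

Standing segments sit a few degrees off vertical, as real limbs do; during
walking the shank swings about the vertical, so the moving prototype's
epoch-mean shank pitch is -90 deg — this is what lets the record's minimum
lower-leg pitch anchor the mounting-offset correction, mirroring the
assumption that every wearer walked at least once.

Realism knobs, all off by default except roll: per-segment orientation
jitter (pitch ~ N(0, jitter_sd^2), held within a segment) plus a small
per-sample tremor (SD = jitter_sd/20); a per-segment roll angle
(~ N(0, roll_sd^2)) about the x axis, which changes neither pitch nor ENMO
but spreads still orientations off a single plane; a constant lower-leg
mounting misalignment added to every shank pitch; per-axis miscalibration
applied as the inverse of the calibration map (so autocalibration must undo
it); and Gaussian machine noise high-passed above 20 Hz.

Movement is a 2 Hz sinusoidal acceleration burst along the instantaneous
gravity axis with random phase; a gravity-parallel burst changes the norm
but not the direction, so pitch is untouched. Its amplitude is solved
numerically so the expected truncated-ENMO epoch mean equals the segment's
target (treadmill medians of ~3.7 mg stationary and ~16.4 mg at 0.1 m/s
motivate the 25 mg default target).

Everything is deterministic given the script's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy import signal as sps
from scipy.optimize import brentq

from .posture import LABELS, LYING, MOVING, SITTING, STANDING
from .sensor_io import LOWER_LEG, THIGH, RawRecording

#: (thigh pitch, lower-leg pitch) in degrees per posture prototype
PROTOTYPES = {
    LYING: (0.0, 0.0),
    SITTING: (0.0, -75.0),
    STANDING: (-85.0, -85.0),
    MOVING: (-85.0, -90.0),
}

BURST_HZ = 2.0
DEFAULT_MOVING_ENMO = 25.0  # mg
TREMOR_FRACTION = 0.05  # per-sample tremor SD as a fraction of jitter_sd


@dataclass
class Segment:
    posture: str
    duration: float  # s
    movement_enmo_target: float = 0.0  # mg; only meaningful for moving segments

    def __post_init__(self) -> None:
        if self.posture not in LABELS:
            raise ValueError(f"unknown posture {self.posture!r}; expected one of {LABELS}")
        if not self.duration > 0:
            raise ValueError("segment duration must be positive")
        if self.posture == MOVING and self.movement_enmo_target == 0.0:
            self.movement_enmo_target = DEFAULT_MOVING_ENMO
        if self.movement_enmo_target > 0 and self.posture != MOVING:
            raise ValueError("movement_enmo_target applies only to moving segments")


@dataclass
class PostureScript:
    """Ground-truth scenario: segments plus realism parameters."""

    segments: Sequence[Segment]
    jitter_sd: float = 0.0  # deg, per-segment pitch jitter
    roll_sd: float = 15.0  # deg, per-segment roll about the x axis
    mounting_offset_lowerleg: float = 0.0  # deg added to every shank pitch
    miscalibration: Optional[tuple] = None  # (offset 3-vector g, gain 3-vector)
    machine_noise_sd: float = 0.0  # mg, >20 Hz band
    seed: int = 0

    def __post_init__(self) -> None:
        self.segments = [
            s if isinstance(s, Segment) else Segment(**s) for s in self.segments
        ]
        if not self.segments:
            raise ValueError("script needs at least one segment")
        if self.miscalibration is not None:
            off, gain = self.miscalibration
            self.miscalibration = (
                np.asarray(off, dtype=float).reshape(3),
                np.asarray(gain, dtype=float).reshape(3),
            )

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    @classmethod
    def from_yaml(cls, path: str) -> "PostureScript":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict) or "segments" not in data:
            raise ValueError("script YAML must be a mapping with a 'segments' list")
        segs = [
            Segment(
                posture=s["posture"],
                duration=float(s["duration"]),
                movement_enmo_target=float(s.get("enmo_target", 0.0)),
            )
            for s in data["segments"]
        ]
        kwargs = {
            k: data[k]
            for k in (
                "jitter_sd",
                "roll_sd",
                "mounting_offset_lowerleg",
                "machine_noise_sd",
                "seed",
            )
            if k in data
        }
        if "miscalibration" in data and data["miscalibration"] is not None:
            mc = data["miscalibration"]
            kwargs["miscalibration"] = (mc["offset"], mc["gain"])
        return cls(segments=segs, **kwargs)


def burst_amplitude(target_mg: float) -> float:
    """Sinusoid amplitude (g) whose expected truncated-ENMO mean is *target_mg*.

    For a burst parallel to gravity the sample norm is ``|1 + A sin(wt)|``;
    the amplitude is found by root-finding on the expectation over one cycle.
    """
    if target_mg <= 0:
        return 0.0
    s = np.sin(np.linspace(0.0, 2.0 * np.pi, 8192, endpoint=False))

    def gap(a: float) -> float:
        return float(np.mean(np.maximum(np.abs(1.0 + a * s) - 1.0, 0.0)) * 1000.0 - target_mg)

    return brentq(gap, 1e-12, 3.0, xtol=1e-12)


def _orientation(pitch_deg: np.ndarray, roll_deg: float) -> np.ndarray:
    """Unit gravity-reaction vectors for given pitch(es) and a fixed roll."""
    th = np.radians(np.atleast_1d(pitch_deg))
    ph = np.radians(roll_deg)
    return np.column_stack(
        [np.sin(th), -np.cos(th) * np.sin(ph), np.cos(th) * np.cos(ph)]
    )


def _machine_noise(rng: np.random.Generator, n: int, fs: float, sd_mg: float) -> np.ndarray:
    """(n, 3) Gaussian noise high-passed above 20 Hz, per-axis SD = sd_mg."""
    white = rng.standard_normal((n, 3))
    sos = sps.butter(4, 20.0, btype="highpass", fs=fs, output="sos")
    hp = sps.sosfilt(sos, white, axis=0)
    scale = hp.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    return hp / scale * (sd_mg / 1000.0)


def generate_pair(
    script: PostureScript, sampling_rate: float = 100.0
) -> tuple[RawRecording, RawRecording, list[str]]:
    """Synthesize the (thigh, lower-leg) raw recordings plus per-epoch truth labels.

    Truth labels use the default 5-s epoch; see :func:`truth_labels` for
    other epoch lengths and boundary-epoch flags.
    """
    rng = np.random.default_rng(script.seed)
    thigh_parts: list[np.ndarray] = []
    ll_parts: list[np.ndarray] = []
    for seg in script.segments:
        n = int(round(seg.duration * sampling_rate))
        proto_t, proto_l = PROTOTYPES[seg.posture]
        pitch_t = proto_t + rng.normal(0.0, script.jitter_sd) if script.jitter_sd else proto_t
        pitch_l = proto_l + rng.normal(0.0, script.jitter_sd) if script.jitter_sd else proto_l
        pitch_l = pitch_l + script.mounting_offset_lowerleg
        roll_t = rng.normal(0.0, script.roll_sd) if script.roll_sd else 0.0
        roll_l = rng.normal(0.0, script.roll_sd) if script.roll_sd else 0.0
        tremor_sd = script.jitter_sd * TREMOR_FRACTION
        if tremor_sd > 0:
            pt = pitch_t + rng.normal(0.0, tremor_sd, n)
            pl = pitch_l + rng.normal(0.0, tremor_sd, n)
        else:
            pt = np.full(n, pitch_t)
            pl = np.full(n, pitch_l)
        seg_t = _orientation(pt, roll_t)
        seg_l = _orientation(pl, roll_l)
        if seg.posture == MOVING:
            amp = burst_amplitude(seg.movement_enmo_target)
            t = np.arange(n) / sampling_rate
            phase = rng.uniform(0.0, 2.0 * np.pi)
            burst = amp * np.sin(2.0 * np.pi * BURST_HZ * t + phase)
            seg_l = seg_l * (1.0 + burst)[:, None]  # along gravity: pitch untouched
        thigh_parts.append(seg_t)
        ll_parts.append(seg_l)
    thigh = np.vstack(thigh_parts)
    lower = np.vstack(ll_parts)
    if script.machine_noise_sd > 0:
        thigh = thigh + _machine_noise(rng, len(thigh), sampling_rate, script.machine_noise_sd)
        lower = lower + _machine_noise(rng, len(lower), sampling_rate, script.machine_noise_sd)
    if script.miscalibration is not None:
        off, gain = script.miscalibration
        # inverse of calibrated = gain * raw + offset
        thigh = (thigh - off) / gain
        lower = (lower - off) / gain
    labels, _ = truth_labels(script, epoch_length=5.0)
    rec_t = RawRecording(site=THIGH, sampling_rate=sampling_rate, samples=thigh,
                         device_id="sim-thigh")
    rec_l = RawRecording(site=LOWER_LEG, sampling_rate=sampling_rate, samples=lower,
                         device_id="sim-lowerleg")
    return rec_t, rec_l, labels


def truth_labels(
    script: PostureScript, epoch_length: float = 5.0
) -> tuple[list[str], np.ndarray]:
    """Per-epoch ground-truth labels and boundary flags.

    An epoch's label is the posture occupying the majority of it; epochs
    straddling a segment boundary are flagged so accuracy scoring can
    exclude them.
    """
    bounds = np.concatenate([[0.0], np.cumsum([s.duration for s in script.segments])])
    n_epochs = int(np.floor(script.total_duration / epoch_length + 1e-9))
    labels: list[str] = []
    boundary = np.zeros(n_epochs, dtype=bool)
    for k in range(n_epochs):
        a, b = k * epoch_length, (k + 1) * epoch_length
        overlaps = np.minimum(b, bounds[1:]) - np.maximum(a, bounds[:-1])
        overlaps = np.maximum(overlaps, 0.0)
        labels.append(script.segments[int(np.argmax(overlaps))].posture)
        boundary[k] = np.count_nonzero(overlaps > 1e-9) > 1
    return labels, boundary
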