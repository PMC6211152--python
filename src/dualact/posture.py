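"""Epoch alignment, mounting-offset correction and the 4-state classifier.

Sign convention: with the device's x axis pointing toward the feet, a
vertical body segment reads a pitch of -90 deg, so "upright" means pitch
near -90. With the upright threshold ``a`` (default 45 deg from horizontal)
every epoch receives exactly one label:

* lower-leg pitch > -a                      -> lying
* lower-leg <= -a, thigh pitch > -a         -> sitting
* both <= -a, lower-leg ENMO <= threshold   -> standing
* both <= -a, lower-leg ENMO  > threshold   -> moving (upright)

Movement is judged only once an epoch is posturally standing, from the
lower-leg ENMO with a strict > 13 mg cut-off. The shank rule is checked
first, so the physically incompatible combination of a vertical thigh with
a horizontal shank falls to "lying".

Because the sensor case is never strapped perfectly parallel to the shank,
all lower-leg pitches are reduced by ``min(pitch) + 90`` before
classification — every wearer is assumed to have brought the shank vertical
(walked) at least once, making the record's minimum pitch a calibration
point at -90 deg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import AlignmentError, CorrectionWarning
from .sensor_io import PipelineConfig
from .signals import EpochSeries

LYING = "lying"
SITTING = "sitting"
STANDING = "standing"
MOVING = "moving"
LABELS = (LYING, SITTING, STANDING, MOVING)


@dataclass
class DualEpochFrame:
    """Time-aligned thigh and lower-leg epochs, optionally labeled.

    ``epoch_starts`` are absolute seconds (thigh start_time included), so the
    frame is self-contained for export. ``correction_offset`` records the
    mounting-offset (degrees) subtracted from the lower-leg pitch, or None
    before correction.
    """

    epoch_starts: np.ndarray
    epoch_length: float
    thigh_pitch: np.ndarray
    lowerleg_pitch: np.ndarray
    lowerleg_enmo: np.ndarray
    labels: Optional[np.ndarray] = None
    correction_offset: Optional[float] = None
    warnings_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epoch_starts = np.asarray(self.epoch_starts, dtype=float)
        self.thigh_pitch = np.asarray(self.thigh_pitch, dtype=float)
        self.lowerleg_pitch = np.asarray(self.lowerleg_pitch, dtype=float)
        self.lowerleg_enmo = np.asarray(self.lowerleg_enmo, dtype=float)
        n = len(self.epoch_starts)
        for arr in (self.thigh_pitch, self.lowerleg_pitch, self.lowerleg_enmo):
            if len(arr) != n:
                raise ValueError("all per-epoch arrays must have equal length")

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_starts)


@dataclass(frozen=True)
class ActivitySummary:
    """Percent of classified epochs spent in each state."""

    pct_lying: float
    pct_sitting: float
    pct_standing: float
    pct_moving: float
    total_hours: float
    n_epochs: int

    def to_dict(self) -> dict:
        return {
            "pct_lying": self.pct_lying,
            "pct_sitting": self.pct_sitting,
            "pct_standing": self.pct_standing,
            "pct_moving": self.pct_moving,
            "total_hours": self.total_hours,
            "n_epochs": self.n_epochs,
        }


def align_epochs(thigh: EpochSeries, lowerleg: EpochSeries) -> DualEpochFrame:
    """Pair thigh and lower-leg epochs on a common grid.

    The grid is anchored at the later-starting series; each of its epochs is
    matched to the nearest epoch of the other series within half an epoch
    length. Epochs without a partner are dropped. Raises
    :class:`~dualact.errors.AlignmentError` when fewer than one pair overlaps.
    """
    if thigh.epoch_length != lowerleg.epoch_length:
        raise AlignmentError("epoch lengths differ between series")
    if thigh.site != "thigh" or lowerleg.site != "lower_leg":
        raise AlignmentError(
            f"expected sites (thigh, lower_leg), got ({thigh.site}, {lowerleg.site})"
        )
    el = thigh.epoch_length
    anchor, other = (thigh, lowerleg) if thigh.start_time >= lowerleg.start_time else (lowerleg, thigh)
    a_starts = anchor.abs_starts()
    o_starts = other.abs_starts()
    # nearest other-epoch for each anchor epoch
    idx = np.searchsorted(o_starts, a_starts)
    lo = np.clip(idx - 1, 0, len(o_starts) - 1)
    hi = np.clip(idx, 0, len(o_starts) - 1)
    nearest = np.where(
        np.abs(o_starts[lo] - a_starts) <= np.abs(o_starts[hi] - a_starts), lo, hi
    )
    ok = np.abs(o_starts[nearest] - a_starts) <= el / 2.0 + 1e-9
    if not np.any(ok):
        raise AlignmentError("the two series do not overlap in time")
    a_idx = np.flatnonzero(ok)
    o_idx = nearest[ok]
    if anchor is thigh:
        t_idx, l_idx = a_idx, o_idx
    else:
        t_idx, l_idx = o_idx, a_idx
    return DualEpochFrame(
        epoch_starts=a_starts[a_idx],
        epoch_length=el,
        thigh_pitch=thigh.mean_pitch[t_idx],
        lowerleg_pitch=lowerleg.mean_pitch[l_idx],
        lowerleg_enmo=lowerleg.mean_enmo[l_idx],
    )


def correct_lowerleg_pitch(
    frame: DualEpochFrame, upright_angle_threshold: float = 45.0
) -> DualEpochFrame:
    """Subtract the mounting offset ``min(lower-leg pitch) + 90`` from the shank pitch.

    After correction the minimum lower-leg epoch pitch is exactly -90 deg.
    The operation is idempotent. If no epoch looks upright (thigh pitch never
    at or below ``-upright_angle_threshold``) the minimum-pitch assumption is
    dubious: the correction is still applied but a
    :class:`~dualact.errors.CorrectionWarning` is emitted and logged on the
    frame.
    """
    if frame.n_epochs < 1:
        raise ValueError("cannot correct an empty frame")
    mn = float(np.min(frame.lowerleg_pitch))
    offset = mn + 90.0
    if offset == 0.0:  # already anchored at -90: exact no-op keeps idempotence
        corrected = frame.lowerleg_pitch.copy()
    else:
        # (x - mn) - 90 rather than x - offset: the minimum maps to -90.0 exactly
        corrected = (frame.lowerleg_pitch - mn) - 90.0
    log = list(frame.warnings_log)
    if not np.any(frame.thigh_pitch <= -upright_angle_threshold):
        msg = (
            "no upright epoch found (thigh pitch never <= "
            f"{-upright_angle_threshold:g} deg); mounting-offset correction of "
            f"{offset:.2f} deg may be biased"
        )
        warnings.warn(msg, CorrectionWarning, stacklevel=2)
        log.append(msg)
    prior = frame.correction_offset or 0.0
    return DualEpochFrame(
        epoch_starts=frame.epoch_starts,
        epoch_length=frame.epoch_length,
        thigh_pitch=frame.thigh_pitch,
        lowerleg_pitch=corrected,
        lowerleg_enmo=frame.lowerleg_enmo,
        labels=frame.labels,
        correction_offset=prior + offset,
        warnings_log=log,
    )


def classify_epoch(
    theta_t: float, theta_l: float, enmo_l: float, config: Optional[PipelineConfig] = None
) -> str:
    """Label one epoch from thigh pitch, corrected lower-leg pitch and lower-leg ENMO."""
    cfg = config or PipelineConfig()
    if not (np.isfinite(theta_t) and np.isfinite(theta_l) and np.isfinite(enmo_l)):
        raise ValueError("classifier inputs must be finite")
    a = cfg.upright_angle_threshold
    if theta_l > -a:
        return LYING
    if theta_t > -a:
        return SITTING
    if enmo_l <= cfg.enmo_moving_threshold:
        return STANDING
    return MOVING


def classify_frame(
    frame: DualEpochFrame, config: Optional[PipelineConfig] = None
) -> DualEpochFrame:
    """Vectorized classification of every epoch; returns a labeled frame."""
    cfg = config or PipelineConfig()
    if not (
        np.all(np.isfinite(frame.thigh_pitch))
        and np.all(np.isfinite(frame.lowerleg_pitch))
        and np.all(np.isfinite(frame.lowerleg_enmo))
    ):
        raise ValueError("classifier inputs must be finite")
    a = cfg.upright_angle_threshold
    labels = np.where(
        frame.lowerleg_pitch > -a,
        LYING,
        np.where(
            frame.thigh_pitch > -a,
            SITTING,
            np.where(frame.lowerleg_enmo <= cfg.enmo_moving_threshold, STANDING, MOVING),
        ),
    ).astype(object)
    return DualEpochFrame(
        epoch_starts=frame.epoch_starts,
        epoch_length=frame.epoch_length,
        thigh_pitch=frame.thigh_pitch,
        lowerleg_pitch=frame.lowerleg_pitch,
        lowerleg_enmo=frame.lowerleg_enmo,
        labels=labels,
        correction_offset=frame.correction_offset,
        warnings_log=list(frame.warnings_log),
    )


def summarize(frame: DualEpochFrame) -> ActivitySummary:
    """Percent of epochs per label plus total recording hours."""
    if frame.labels is None or frame.n_epochs == 0:
        raise ValueError("summarize requires a non-empty labeled frame")
    n = frame.n_epochs
    counts = {lab: int(np.sum(frame.labels == lab)) for lab in LABELS}
    return ActivitySummary(
        pct_lying=100.0 * counts[LYING] / n,
        pct_sitting=100.0 * counts[SITTING] / n,
        pct_standing=100.0 * counts[STANDING] / n,
        pct_moving=100.0 * counts[MOVING] / n,
        total_hours=n * frame.epoch_length / 3600.0,
        n_epochs=n,
    )


def timeline_export(frame: DualEpochFrame) -> list[tuple[float, float, str]]:
    """Run-length encode consecutive identical labels as (start, end, label)."""
    if frame.labels is None:
        raise ValueError("timeline export requires a labeled frame")
    runs: list[tuple[float, float, str]] = []
    starts = frame.epoch_starts
    el = frame.epoch_length
    run_start = starts[0]
    cur = frame.labels[0]
    for s, lab in zip(starts[1:], frame.labels[1:]):
        if lab != cur:
            runs.append((float(run_start), float(s), str(cur)))
            run_start, cur = s, lab
    runs.append((float(run_start), float(starts[-1] + el), str(cur)))
    return runs
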