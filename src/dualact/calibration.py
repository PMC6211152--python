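"""Gravity autocalibration of raw acceleration.

An ideal, motionless accelerometer measures exactly 1 g regardless of
orientation, so each still period yields one point that should lie on the
unit sphere. Per-axis offset and gain are estimated by least squares so that
the calibrated still vectors have unit norm; the fit is pooled over all data
from one device. With thigh/shank wear the sampled orientations can be
nearly collinear, in which case a 6-parameter fit is unidentifiable; a
sphere-coverage guard then falls back to an offset-only fit flagged as not
converged.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .errors import CalibrationUnavailableError
from .sensor_io import RawRecording

#: minimum angular spread (degrees) of still orientations for a full gain fit
MIN_COVERAGE_DEG = 30.0

#: stop when the mean residual improves by less than this (g) per iteration
CONVERGENCE_TOL = 1e-9
MAX_ITER = 1000

GAIN_RANGE = (0.8, 1.2)
OFFSET_RANGE = (-0.25, 0.25)  # g


@dataclass
class CalibrationParams:
    """Per-axis affine map ``calibrated = gain * raw + offset`` (units: g)."""

    offset: np.ndarray
    gain: np.ndarray
    n_still_windows: int
    residual: float  # mean | ||calibrated still vector|| - 1 | in mg
    converged: bool

    def __post_init__(self) -> None:
        self.offset = np.asarray(self.offset, dtype=float).reshape(3)
        self.gain = np.asarray(self.gain, dtype=float).reshape(3)

    @classmethod
    def identity(cls, n_still_windows: int = 0) -> "CalibrationParams":
        return cls(
            offset=np.zeros(3),
            gain=np.ones(3),
            n_still_windows=n_still_windows,
            residual=float("nan"),
            converged=False,
        )

    def is_identity(self) -> bool:
        return bool(np.all(self.offset == 0.0) and np.all(self.gain == 1.0))

    def to_dict(self) -> dict:
        return {
            "offset": self.offset.tolist(),
            "gain": self.gain.tolist(),
            "n_still_windows": self.n_still_windows,
            "residual_mg": None if np.isnan(self.residual) else self.residual,
            "converged": self.converged,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def find_still_windows(
    rec: RawRecording, window: float = 10.0, sd_threshold: float = 13.0
) -> np.ndarray:
    """Mean (x, y, z) of each non-overlapping still window.

    A window of *window* seconds is still when the per-axis sample standard
    deviation is below *sd_threshold* (mg) on all three axes. Returns a
    (k, 3) array; k may be 0.
    """
    if rec.duration < window:
        raise ValueError("recording shorter than one calibration window")
    n_per = int(round(window * rec.sampling_rate))
    n_win = rec.n_samples // n_per
    blocks = rec.samples[: n_win * n_per].reshape(n_win, n_per, 3)
    sd_mg = blocks.std(axis=1, ddof=0) * 1000.0
    still = np.all(sd_mg < sd_threshold, axis=1)
    return blocks[still].mean(axis=1)


def _mean_abs_residual_mg(means: np.ndarray, offset: np.ndarray, gain: np.ndarray) -> float:
    norms = np.linalg.norm(means * gain + offset, axis=1)
    return float(np.mean(np.abs(norms - 1.0)) * 1000.0)


def _gauss_newton(means: np.ndarray, fit_gain: bool) -> tuple[np.ndarray, np.ndarray, bool]:
    """Minimize sum((||gain*v + offset|| - 1)^2); returns (offset, gain, converged)."""
    offset = np.zeros(3)
    gain = np.ones(3)
    prev = _mean_abs_residual_mg(means, offset, gain) / 1000.0
    converged = False
    for _ in range(MAX_ITER):
        cal = means * gain + offset
        norms = np.linalg.norm(cal, axis=1)
        norms = np.where(norms == 0, 1.0, norms)
        unit = cal / norms[:, None]
        resid = norms - 1.0
        if fit_gain:
            jac = np.hstack([unit, unit * means])  # d/d offset, d/d gain
        else:
            jac = unit
        step, *_ = np.linalg.lstsq(jac, -resid, rcond=None)
        offset = offset + step[:3]
        if fit_gain:
            gain = gain + step[3:]
        cur = _mean_abs_residual_mg(means, offset, gain) / 1000.0
        if abs(prev - cur) < CONVERGENCE_TOL:
            converged = True
            break
        prev = cur
    return offset, gain, converged


def _coverage_deg(means: np.ndarray) -> float:
    """Largest angle (degrees) between a still direction and the mean direction."""
    norms = np.linalg.norm(means, axis=1)
    unit = means / np.where(norms == 0, 1.0, norms)[:, None]
    center = unit.mean(axis=0)
    cn = np.linalg.norm(center)
    if cn == 0:
        return 180.0
    center /= cn
    cosang = np.clip(unit @ center, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)).max())


def fit_calibration(still_means: np.ndarray) -> CalibrationParams:
    """Fit per-axis offset and gain from still-window mean vectors.

    Requires at least two still means. When the sampled orientations all lie
    within :data:`MIN_COVERAGE_DEG` of one direction the gain is
    unidentifiable; an offset-only fit is returned with ``converged=False``.
    Fits with gain outside [0.8, 1.2] or offset outside +/-0.25 g are also
    flagged as not converged.
    """
    still_means = np.asarray(still_means, dtype=float).reshape(-1, 3)
    if len(still_means) < 2:
        raise CalibrationUnavailableError(
            f"need >= 2 still windows to calibrate, found {len(still_means)}"
        )
    poor_coverage = _coverage_deg(still_means) < MIN_COVERAGE_DEG
    offset, gain, converged = _gauss_newton(still_means, fit_gain=not poor_coverage)
    if poor_coverage:
        converged = False
    in_range = bool(
        np.all((gain >= GAIN_RANGE[0]) & (gain <= GAIN_RANGE[1]))
        and np.all((offset >= OFFSET_RANGE[0]) & (offset <= OFFSET_RANGE[1]))
    )
    return CalibrationParams(
        offset=offset,
        gain=gain,
        n_still_windows=len(still_means),
        residual=_mean_abs_residual_mg(still_means, offset, gain),
        converged=converged and in_range,
    )


def apply_calibration(rec: RawRecording, params: CalibrationParams) -> RawRecording:
    """Return a new recording with ``gain * v + offset`` applied per sample."""
    if not (np.all(np.isfinite(params.offset)) and np.all(np.isfinite(params.gain))):
        raise ValueError("calibration parameters must be finite")
    return RawRecording(
        site=rec.site,
        sampling_rate=rec.sampling_rate,
        samples=rec.samples * params.gain + params.offset,
        start_time=rec.start_time,
        device_id=rec.device_id,
        calibrated=True,
    )
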