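"""Sample-level signals (filtered acceleration, ENMO, pitch) and epoch summaries.

ENMO (Euclidean Norm Minus One) is the vector magnitude of the tri-axial
acceleration minus 1 g, truncated at zero per sample and expressed in mg; it
isolates movement-related acceleration from gravity. Pitch is the elevation
of the device's primary (x) axis relative to the horizontal plane:
``atan2(x, sqrt(y^2 + z^2))`` in degrees, so +/-90 deg means the x axis is
parallel to gravity and 0 deg perpendicular to it.

Both signals are computed on the calibrated, low-pass-filtered stream, then
averaged into fixed-length epochs (default 5 s). Truncation of ENMO happens
per sample, before averaging, so a quiet epoch is exactly zero. Pitch is
averaged as the mean of per-sample pitch angles. Filtering is a single
forward pass of a 4th-order Butterworth, which keeps the empirical -3 dB
point at the configured cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import EmptySeriesError
from .sensor_io import RawRecording


def lowpass(rec: RawRecording, cutoff: float = 20.0) -> RawRecording:
    """4th-order Butterworth low-pass, one forward pass per axis."""
    nyq = rec.sampling_rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz, got {cutoff}")
    sos = sps.butter(4, cutoff, btype="lowpass", fs=rec.sampling_rate, output="sos")
    filtered = sps.sosfilt(sos, rec.samples, axis=0)
    return RawRecording(
        site=rec.site,
        sampling_rate=rec.sampling_rate,
        samples=filtered,
        start_time=rec.start_time,
        device_id=rec.device_id,
        calibrated=rec.calibrated,
    )


def enmo_sample(v) -> np.ndarray | float:
    """Truncated Euclidean-norm-minus-one in mg: ``max(||v|| - 1, 0) * 1000``.

    Accepts a single 3-vector or an (n, 3) array (returns an n-vector).
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("acceleration vector must be finite")
    norm = np.linalg.norm(v, axis=-1)
    return np.maximum(norm - 1.0, 0.0) * 1000.0


def pitch_sample(v) -> np.ndarray | float:
    """Pitch of the x axis in degrees, in [-90, +90].

    ``atan2(x, sqrt(y^2 + z^2))``; when y = z = 0 the sign of x selects
    +/-90. The zero vector has no orientation and raises ValueError.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("acceleration vector must be finite")
    norm = np.linalg.norm(v, axis=-1)
    if np.any(norm == 0):
        raise ValueError("pitch is undefined for the zero vector")
    x = v[..., 0]
    horiz = np.hypot(v[..., 1], v[..., 2])
    return np.degrees(np.arctan2(x, horiz))


@dataclass
class EpochSeries:
    """Per-epoch mean pitch (degrees) and mean ENMO (mg) for one site."""

    site: str
    epoch_length: float
    epoch_starts: np.ndarray  # seconds from record start, spacing == epoch_length
    mean_pitch: np.ndarray
    mean_enmo: np.ndarray
    start_time: float = 0.0  # absolute seconds; aligns the two sensors

    def __post_init__(self) -> None:
        self.epoch_starts = np.asarray(self.epoch_starts, dtype=float)
        self.mean_pitch = np.asarray(self.mean_pitch, dtype=float)
        self.mean_enmo = np.asarray(self.mean_enmo, dtype=float)

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_starts)

    def abs_starts(self) -> np.ndarray:
        return self.epoch_starts + self.start_time


def epochize(rec: RawRecording, epoch_length: float = 5.0) -> EpochSeries:
    """Average sample-level pitch and ENMO into consecutive epochs.

    Epochs tile the record from its start; a trailing partial epoch is
    dropped. A record shorter than one epoch raises
    :class:`~dualact.errors.EmptySeriesError`.
    """
    spe = epoch_length * rec.sampling_rate  # samples per epoch
    n_epochs = int(np.floor(rec.n_samples / spe + 1e-9))
    if n_epochs < 1:
        raise EmptySeriesError(
            f"record of {rec.duration:.2f} s is shorter than one {epoch_length} s epoch"
        )
    edges = np.round(np.arange(n_epochs + 1) * spe).astype(int)
    used = rec.samples[: edges[-1]]  # drop the trailing partial epoch
    pitch = pitch_sample(used)
    enmo = enmo_sample(used)
    mean_pitch = np.add.reduceat(pitch, edges[:-1]) / np.diff(edges)
    mean_enmo = np.add.reduceat(enmo, edges[:-1]) / np.diff(edges)
    return EpochSeries(
        site=rec.site,
        epoch_length=epoch_length,
        epoch_starts=np.arange(n_epochs) * epoch_length,
        mean_pitch=mean_pitch,
        mean_enmo=mean_enmo,
        start_time=rec.start_time,
    )
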