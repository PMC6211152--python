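"""Reading and writing recordings, epoch tables and pipeline configuration.

Raw input is one time-stamped CSV per sensor with header ``time,x,y,z``:
``time`` in seconds from start (float) or ISO-8601, ``x/y/z`` in g. The x
axis is the device's long axis, mounted pointing toward the feet. Irregular
sampling (inter-sample intervals deviating more than 1% from the median) is
rejected rather than resampled.

All floating-point output is written at fixed precision so repeated runs
produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, RateMismatchWarning, RawDataError, RawFormatError

THIGH = "thigh"
LOWER_LEG = "lower_leg"
SITES = (THIGH, LOWER_LEG)

RAW_COLUMNS = ("time", "x", "y", "z")

#: tolerated relative deviation of inter-sample intervals from their median
RATE_TOLERANCE = 0.01


@dataclass
class RawRecording:
    """One sensor's tri-axial acceleration time series in g units.

    ``samples`` is an (n, 3) float array; rows are uniformly spaced at
    ``1/sampling_rate`` seconds. ``start_time`` is the absolute start in
    seconds (e.g. Unix epoch seconds, or 0 for relative recordings) and is
    what aligns the two sensors of a pair.
    """

    site: str
    sampling_rate: float
    samples: np.ndarray
    start_time: float = 0.0
    device_id: str = ""
    calibrated: bool = False

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}; expected one of {SITES}")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")
        if len(self.samples) < 1:
            raise ValueError("recording must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds from start."""
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the processing pipeline.

    Defaults encode the published protocol: 5-s epochs, a 20 Hz low-pass
    against machine noise, a >13 mg lower-leg ENMO cut-off for movement, a
    45-degrees-from-horizontal posture threshold, and a 10-s / 13 mg still
    criterion for gravity autocalibration.
    """

    epoch_length: float = 5.0  # s
    lowpass_cutoff: float = 20.0  # Hz
    enmo_moving_threshold: float = 13.0  # mg
    upright_angle_threshold: float = 45.0  # degrees from horizontal
    calibration_window: float = 10.0  # s
    calibration_still_sd: float = 13.0  # mg

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ConfigError(f"{f.name} must be strictly positive, got {v!r}")
        if not 0 < self.upright_angle_threshold < 90:
            raise ConfigError(
                "upright_angle_threshold must lie in (0, 90) degrees, got "
                f"{self.upright_angle_threshold!r}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: Optional[str] = None) -> PipelineConfig:
    """Load a YAML configuration, or the defaults when *path* is None.

    Unknown keys are rejected so typos do not silently fall back to defaults.
    """
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def _times_to_seconds(col: pd.Series) -> tuple[np.ndarray, float]:
    """Normalize the time column to seconds-from-start; return (t, start_time)."""
    if pd.api.types.is_numeric_dtype(col):
        t = col.to_numpy(dtype=float)
        return t - t[0], float(t[0])
    ts = pd.to_datetime(col, utc=True, format="ISO8601")
    t = ts.astype("int64").to_numpy() / 1e9
    return t - t[0], float(t[0])


def read_raw_csv(
    path: str, site: str, declared_rate: Optional[float] = None
) -> RawRecording:
    """Read one sensor's raw CSV into a :class:`RawRecording`.

    The sampling rate is inferred from the median inter-sample interval. If
    *declared_rate* is given and the inferred rate deviates from it by more
    than 1%, a :class:`RateMismatchWarning` is emitted (the inferred rate
    wins). Non-monotonic or irregular time stamps raise
    :class:`RawDataError`.
    """
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise RawFormatError(f"{path}: could not parse CSV: {exc}") from exc
    for col in RAW_COLUMNS:
        if col not in df.columns:
            raise RawFormatError(f"{path}: missing required column {col!r}")
    t, start_time = _times_to_seconds(df["time"])
    if len(t) < 2:
        raise RawDataError(f"{path}: need at least 2 samples to infer a rate")
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        raise RawDataError(
            f"{path}: time not monotonically increasing at row {int(bad[0]) + 1}"
        )
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > RATE_TOLERANCE * med:
        worst = int(np.argmax(np.abs(dt - med))) + 1
        raise RawDataError(
            f"{path}: irregular sampling (interval at row {worst} deviates "
            f">{RATE_TOLERANCE:.0%} from the median); resampling is not supported"
        )
    rate = 1.0 / med
    if abs(rate - round(rate)) < 1e-3:  # snap float noise on nominal rates
        rate = float(round(rate))
    if declared_rate is not None and abs(rate - declared_rate) > 0.01 * declared_rate:
        warnings.warn(
            f"{path}: inferred rate {rate:.3f} Hz deviates >1% from declared "
            f"{declared_rate:.3f} Hz",
            RateMismatchWarning,
            stacklevel=2,
        )
    samples = df[["x", "y", "z"]].to_numpy(dtype=float)
    return RawRecording(
        site=site, sampling_rate=rate, samples=samples, start_time=start_time
    )


def write_raw_csv(path: str, rec: RawRecording) -> None:
    """Write a recording in the raw CSV format (time %.6f s, axes %.6f g)."""
    t = rec.times() + rec.start_time
    with open(path, "w", newline="") as fh:
        fh.write("time,x,y,z\n")
        for ti, (x, y, z) in zip(t, rec.samples):
            fh.write(f"{ti:.6f},{x:.6f},{y:.6f},{z:.6f}\n")


def write_epoch_csv(path: str, frame) -> None:
    """Write a labeled :class:`~dualact.posture.DualEpochFrame` byte-stably.

    Columns: epoch_start, thigh_pitch_deg, lowerleg_pitch_deg,
    lowerleg_enmo_mg, label; floats at fixed 4-decimal precision.
    """
    if frame.n_epochs == 0:
        raise ValueError("cannot write an empty epoch frame")
    if frame.labels is None:
        raise ValueError("frame must be labeled before writing")
    with open(path, "w", newline="") as fh:
        fh.write("epoch_start,thigh_pitch_deg,lowerleg_pitch_deg,lowerleg_enmo_mg,label\n")
        for s, tp, lp, e, lab in zip(
            frame.epoch_starts,
            frame.thigh_pitch,
            frame.lowerleg_pitch,
            frame.lowerleg_enmo,
            frame.labels,
        ):
            fh.write(f"{s:.4f},{tp:.4f},{lp:.4f},{e:.4f},{lab}\n")


def read_epoch_csv(path: str):
    """Read an epoch CSV written by :func:`write_epoch_csv` back into a frame."""
    from .posture import DualEpochFrame  # deferred: avoids an import cycle

    df = pd.read_csv(path)
    expected = [
        "epoch_start",
        "thigh_pitch_deg",
        "lowerleg_pitch_deg",
        "lowerleg_enmo_mg",
        "label",
    ]
    for col in expected:
        if col not in df.columns:
            raise RawFormatError(f"{path}: missing required column {col!r}")
    starts = df["epoch_start"].to_numpy(dtype=float)
    epoch_length = float(np.median(np.diff(starts))) if len(starts) > 1 else 5.0
    return DualEpochFrame(
        epoch_starts=starts,
        epoch_length=epoch_length,
        thigh_pitch=df["thigh_pitch_deg"].to_numpy(dtype=float),
        lowerleg_pitch=df["lowerleg_pitch_deg"].to_numpy(dtype=float),
        lowerleg_enmo=df["lowerleg_enmo_mg"].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=object),
    )
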