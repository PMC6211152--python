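"""Exception and warning types shared across the pipeline."""


class RawFormatError(ValueError):
    """A raw CSV file is structurally malformed (e.g. a required column is missing)."""


class RawDataError(ValueError):
    """A raw CSV file parses but violates a data contract (non-monotonic or irregular time)."""


class ConfigError(ValueError):
    """A pipeline configuration file is invalid."""


class CalibrationUnavailableError(RuntimeError):
    """Too few still periods to fit a calibration; callers fall back to identity."""


class AlignmentError(ValueError):
    """The two sensors' epoch series do not overlap in time."""


class EmptySeriesError(ValueError):
    """A recording is too short to produce a single epoch."""


class RateMismatchWarning(UserWarning):
    """Observed sampling rate deviates from the declared rate by more than 1%."""


class CorrectionWarning(UserWarning):
    """Mounting-offset correction applied to a record with no apparent upright epoch."""


class CalibrationWarning(UserWarning):
    """Calibration fell back to identity or did not converge."""
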