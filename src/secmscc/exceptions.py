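"""Exception hierarchy.

``SecmSccError`` is the common base so callers can catch everything the
package raises with one clause. ``ConfigError`` is kept distinct from data
errors because the command-line interface maps them to different exit codes
(2 vs 1).
"""


class SecmSccError(Exception):
    """Base class for all errors raised by secmscc."""


class DomainError(SecmSccError, ValueError):
    """An argument is outside the physically meaningful domain."""


class InfeasibleRateError(DomainError):
    """A demanded respiration rate would require a negative surface
    oxygen concentration (the hemispherical steady state cannot supply it)."""


class InsufficientDataError(SecmSccError):
    """A trace or table does not contain enough data for the operation."""


class FormatError(SecmSccError, ValueError):
    """An input file does not conform to the expected dialect."""


class ConfigError(SecmSccError, ValueError):
    """A configuration document is invalid (unknown keys, bad values)."""


class PipelineStageError(SecmSccError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original}")


class ExtrapolationWarning(UserWarning):
    """A calibration curve was evaluated outside its fitted range."""
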