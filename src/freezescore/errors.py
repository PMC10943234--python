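"""Exception hierarchy.

All package errors derive from :class:`FreezeScoreError` so callers can
catch pipeline failures with a single except clause while still
distinguishing input problems from degenerate-data conditions that call
for manual review.
"""


class FreezeScoreError(Exception):
    """Base class for all freezescore errors."""


class InputError(FreezeScoreError, ValueError):
    """Malformed or inconsistent user input (shapes, ranges, missing data)."""


class ConfigError(FreezeScoreError, ValueError):
    """Invalid configuration value (e.g. even median kernel)."""


class VideoDecodeError(FreezeScoreError, IOError):
    """A video file could not be decoded into frames."""


class DegenerateTraceError(FreezeScoreError):
    """The similarity trace carries no usable signal (e.g. every score is
    at or below the outlier threshold, or all scores are identical).

    Sessions raising this need manual handling: the subject either never
    moved or never stopped moving, and the semi-automated contract
    requires a human to set component point estimates."""


class DegenerateModelError(FreezeScoreError):
    """A mixture fit cannot proceed (all-identical scores)."""


class UndefinedStatisticError(FreezeScoreError):
    """A statistic is undefined for the given data (zero variance,
    constant series, single-class truth vector)."""


class SamplingError(FreezeScoreError):
    """Segment sampling could not satisfy the request."""

    def __init__(self, message: str, deficient_class: str | None = None):
        super().__init__(message)
        self.deficient_class = deficient_class


class ConsistencyError(FreezeScoreError):
    """Internal invariant violated (e.g. overlapping bouts)."""
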