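"""Exception hierarchy. Everything derives from GaitBbsError; most types
also subclass ValueError so generic callers can catch either."""

from __future__ import annotations

__all__ = [
    "GaitBbsError",
    "FormatError",
    "DataError",
    "TimingError",
    "RangeError",
    "DuplicateSubjectError",
    "ConfigError",
    "LengthError",
    "DegenerateBaselineError",
    "TriggerNotFoundError",
    "TooShortError",
    "MissingLabelError",
    "ShapeError",
    "DomainError",
]


class GaitBbsError(Exception):
    """Base class for all pipeline errors."""


class FormatError(GaitBbsError, ValueError):
    """A file does not have the expected column structure."""


class DataError(GaitBbsError, ValueError):
    """Missing or non-finite values in loaded data."""


class TimingError(GaitBbsError, ValueError):
    """Timestamps inconsistent with the declared sample rate."""


class RangeError(GaitBbsError, ValueError):
    """A value outside its documented range (e.g. BBS score not in 0-56)."""


class DuplicateSubjectError(GaitBbsError, ValueError):
    """The same subject_id appears more than once in a label table."""


class ConfigError(GaitBbsError, ValueError):
    """Invalid configuration (e.g. cutoff at or above Nyquist)."""


class LengthError(GaitBbsError, ValueError):
    """A signal is too short for the requested filter."""


class DegenerateBaselineError(GaitBbsError, ValueError):
    """A static-baseline channel has (near-)zero standard deviation."""


class TriggerNotFoundError(GaitBbsError, ValueError):
    """No qualifying peak on the trigger channel."""


class TooShortError(GaitBbsError, ValueError):
    """A recording is shorter than one window after truncation."""


class MissingLabelError(GaitBbsError, KeyError):
    """A recording has no matching label row."""


class ShapeError(GaitBbsError, ValueError):
    """Mismatched array lengths/shapes."""


class DomainError(GaitBbsError, ValueError):
    """Empty input where at least one element is required."""
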