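"""Exception hierarchy.

All validation failures raise a subclass of :class:`NeuromidiError` so callers
(and the CLI) can distinguish data problems from programming errors.
"""


class NeuromidiError(Exception):
    """Base class for all package errors."""


class EventFileError(NeuromidiError):
    """An event file could not be read or failed validation."""


class MissingFileError(EventFileError):
    """A required input file or directory is absent."""


class EmptyFileError(EventFileError):
    """An event file contains no data rows."""


class NonNumericTimeError(EventFileError):
    """An event time could not be parsed as a number."""


class NegativeTimeError(EventFileError):
    """An event time is negative (times are seconds from recording start)."""


class SpikeSortingFormatError(NeuromidiError):
    """A spike-sorting output directory violates the expected convention."""


class LengthMismatchError(SpikeSortingFormatError):
    """Spike-time and cluster-id arrays have different lengths."""


class SamplingRateError(SpikeSortingFormatError):
    """The declared sampling rate is missing or non-positive."""


class PitchRangeError(NeuromidiError):
    """A pitch fell outside the MIDI range 0-127."""


class PitchMapError(NeuromidiError):
    """A pitch assignment is invalid (duplicate ids, unmapped identity...)."""


class RateError(NeuromidiError):
    """An instantaneous-rate computation is ill-defined (too few events,
    duplicate timestamps, non-positive rate)."""


class ConfigError(NeuromidiError):
    """A sonification configuration value is out of its valid range."""


class SMFError(NeuromidiError):
    """A Standard MIDI File is malformed or cannot be paired note-on/off."""
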