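"""Exception hierarchy.

Every error raised by the package derives from :class:`BarovarError`, so callers
can catch one type at the CLI boundary.  Names follow the condition they signal.
"""


class BarovarError(Exception):
    """Base class for all package errors."""


class ParseError(BarovarError, ValueError):
    """A file could not be parsed; the message names the offending row."""


class MissingColumn(ParseError):
    """A mandatory header column is absent from a beat CSV."""


class NonUniformSampling(ParseError):
    """Waveform time column deviates from the declared sampling rate."""


class MonotonicityViolated(BarovarError, ValueError):
    """Beat times are not strictly increasing."""


class NoBeatsDetected(BarovarError):
    """No pulse satisfied the prominence/refractory constraints."""


class WindowTooShort(BarovarError, ValueError):
    """Recording shorter than one analysis window."""


class TooFewBeats(BarovarError, ValueError):
    """Fewer beats than the operation needs."""


class SeriesTooShort(BarovarError, ValueError):
    """Evenly sampled series shorter than a filter kernel."""


class SeriesShorterThanNfft(BarovarError, ValueError):
    """Evenly sampled series shorter than one FFT segment."""


class DegenerateFit(BarovarError, ValueError):
    """Regression abscissa has zero variance."""


class UnknownPreset(BarovarError, KeyError):
    """Simulator preset name not recognised."""


class RateTooLow(BarovarError, ValueError):
    """Waveform rendering rate below the supported minimum."""


class EmptyGroup(BarovarError, ValueError):
    """Descriptive summary requested for an empty collection."""
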