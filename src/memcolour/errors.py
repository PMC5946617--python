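"""Exception hierarchy.

Everything raised intentionally by this package derives from
:class:`MemColourError`, so callers can catch one type at pipeline
boundaries while tests can assert on the specific failure mode.
"""


class MemColourError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MemColourError, ValueError):
    """Non-finite, empty, or otherwise malformed numeric input."""


class InvalidAxisError(MemColourError, ValueError):
    """A hue axis that is not unit-norm was passed to a projection."""


class DegenerateAxisError(MemColourError):
    """The mean typical adjustment is too close to the origin to define
    a memory-colour direction (e.g. a truly achromatic control object)."""


class InsufficientDataError(MemColourError):
    """Too few samples, pairs, or observers for the requested statistic."""


class DegenerateCueError(MemColourError):
    """A cue with zero variance (infinite reliability) was used without
    opting in to epsilon-regularisation."""


class LevelMismatchError(MemColourError):
    """Prior and signal cues estimated at different analysis levels were
    combined; fusing a per-observer cue with an aggregate cue is a bug."""


class OutOfRangeError(MemColourError, ValueError):
    """A correlation coefficient outside the open interval (-1, 1)."""


class DataFormatError(MemColourError, ValueError):
    """An adjustments table violates the CSV schema; the message names the
    offending row and column."""


class ConfigError(MemColourError, ValueError):
    """A run or generator configuration failed validation."""
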