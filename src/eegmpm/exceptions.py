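"""Exception hierarchy.

Two broad families matter to callers (and to the CLI exit codes):
configuration problems (bad parameters, unknown profiles) and data problems
(malformed files, degenerate or too-short signals).
"""


class EegmpmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EegmpmError):
    """Invalid parameter combination or unknown profile/class name."""


class DataError(EegmpmError):
    """Base class for problems with the input data itself."""


class BonnFormatError(DataError):
    """A Bonn-format ASCII file could not be parsed."""


class DegenerateSignalError(DataError):
    """Signal has zero variance where nonzero variance is required."""


class InsufficientDataError(DataError):
    """Too few samples/vectors for the requested operation."""


class StratificationError(DataError):
    """A class has too few segments for a stratified split."""


class UndefinedEntropyError(DataError):
    """Sample entropy undefined: no template matches at one of the lengths."""


class InseparableMeansError(DataError):
    """MPM cannot be solved: the two class means coincide."""


class ShapeError(DataError):
    """Vector dimensionality does not match the fitted object."""
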