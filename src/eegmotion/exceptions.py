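"""Exception hierarchy shared across the package.

All errors derive from :class:`EEGMotionError` so callers can catch the
package's failures with a single except clause while still distinguishing
configuration mistakes from degenerate numeric inputs.
"""


class EEGMotionError(Exception):
    """Base class for every error raised by eegmotion."""


class ConfigurationError(EEGMotionError, ValueError):
    """A parameter violates its documented constraint (e.g. even median window)."""


class ParseError(EEGMotionError, ValueError):
    """A signal file contains a cell that does not parse as a number."""


class VocabularyError(EEGMotionError, ValueError):
    """A label is not present in the dataset's label vocabulary."""


class InputTooShortError(EEGMotionError, ValueError):
    """A signal is too short for the requested framing or decomposition."""


class UndefinedInputError(EEGMotionError, ValueError):
    """A descriptor is mathematically undefined for this input (e.g. zero spectrum)."""


class DegenerateInputError(EEGMotionError, ValueError):
    """An input is degenerate for the operation (e.g. zero-RMS channel for AWGN)."""


class CodecError(EEGMotionError, ValueError):
    """A flat parameter vector does not match the network architecture."""
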