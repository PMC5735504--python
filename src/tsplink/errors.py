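"""Exception hierarchy used across the pipeline."""


class TsplinkError(Exception):
    """Base class for all package errors."""


class FormatError(TsplinkError, ValueError):
    """A file does not conform to the expected layout (ragged rows, non-square matrix, ...)."""


class ValidationError(TsplinkError, ValueError):
    """Data violates an invariant (duplicate marker names, out-of-range rf, ...)."""


class CodingError(TsplinkError, ValueError):
    """A genotype token is not covered by the supplied coding map."""


class ParameterError(TsplinkError, ValueError):
    """A user-supplied parameter is outside its legal range."""


class UndefinedRfError(TsplinkError, ValueError):
    """A marker pair has no informative individuals, so rf cannot be estimated."""


class SizeError(TsplinkError, ValueError):
    """An instance exceeds the exact solver's vertex limit."""


class InfiniteDistanceError(TsplinkError, ValueError):
    """An adjacent rf of 0.5 maps to infinite distance under the chosen map function."""
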