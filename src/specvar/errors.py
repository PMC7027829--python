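"""Exception hierarchy.

All user-facing failures raise a subclass of :class:`SpecvarError` so callers
(and the CLI) can distinguish bad inputs from genuine bugs.
"""


class SpecvarError(Exception):
    """Base class for all specvar errors."""


class ValidationError(SpecvarError):
    """An input object violates its invariants (shapes, ordering, ranges)."""


class ParameterError(SpecvarError):
    """A parameter value is outside its documented domain."""


class EmptySpectrumError(SpecvarError):
    """Band trimming removed every band."""


class NoValidPixelsError(SpecvarError):
    """No usable vegetated pixels remain after masking."""


class InternalConsistencyError(SpecvarError):
    """A mathematical identity the method guarantees failed numerically.

    Raised (never silently ignored) when e.g. the additive decomposition of
    the total sum of squares does not hold to tolerance.
    """
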