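"""Exception hierarchy shared across the package."""


class RTQWTError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(RTQWTError, ValueError):
    """A transform/optimizer/kernel parameter is outside its valid domain."""


class InvalidInputError(RTQWTError, ValueError):
    """An input array or dataset violates a precondition."""


class LevelOverflowError(RTQWTError, ValueError):
    """Requested decomposition depth exceeds what the signal length allows."""


class StructureError(RTQWTError, ValueError):
    """A subband set is internally inconsistent (lengths vs. parameters)."""


class DegenerateInputError(RTQWTError, ValueError):
    """Input is degenerate for the requested statistic (e.g. constant series)."""


class NumericalError(RTQWTError, ArithmeticError):
    """A numerical computation failed (non-finite fitness, singular system)."""
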