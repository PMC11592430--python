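"""Exception hierarchy for the derangetropy package."""


class DerangetropyError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedFamilyError(DerangetropyError, ValueError):
    """Requested distribution family is not one of the supported ones."""


class InvalidParameterError(DerangetropyError, ValueError):
    """Family parameters violate their constraints (scale <= 0, a >= b, ...)."""


class InvalidInputError(DerangetropyError, ValueError):
    """Raw input contains non-finite or otherwise unusable values."""


class DegenerateSampleError(DerangetropyError, ValueError):
    """Sample is too small or has zero variance for density estimation."""


class DomainError(DerangetropyError, ValueError):
    """Argument lies outside the mathematical domain of the operation."""


class NumericalIntegrationError(DerangetropyError, RuntimeError):
    """Adaptive quadrature failed to converge; carries solver diagnostics."""


class CorruptedCurveError(DerangetropyError, ValueError):
    """A DerangetropyCurve no longer satisfies its mass invariant."""


class InsufficientDataError(DerangetropyError, ValueError):
    """Not enough points/rows to perform the requested operation."""


class CoverageError(DerangetropyError, ValueError):
    """Evaluation grid does not reach the region the operation needs."""


class SignalFormatError(DerangetropyError, ValueError):
    """Delimited signal file violates the expected matrix layout."""


class EmptyResultError(DerangetropyError, ValueError):
    """Every channel was skipped; nothing to analyze."""
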